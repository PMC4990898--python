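"""Atomic structure container used across reconstruction and energetics.

A thin columnar container (numpy arrays, one row per atom) carrying the
fields the package needs: names, residue labels, chains, coordinates,
optional partial charges (e) and intrinsic radii (A), and a backbone flag.
``segment`` tracks which dimer a chain belongs to in assembled filaments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AtomicStructure", "StructureError", "chain_ids"]


class StructureError(ValueError):
    pass


def chain_ids(n: int) -> list[str]:
    """Chain identifiers cycled A-Z, then two-letter ids AA, AB, ..."""
    letters = [chr(ord("A") + i) for i in range(26)]
    out = list(letters)
    i = 0
    while len(out) < n:
        out.append(letters[i // 26] + letters[i % 26])
        i += 1
    return out[:n]


@dataclass
class AtomicStructure:
    """Columnar atom table.

    ``charges`` and ``radii`` must be present for all atoms or absent
    (None); residue numbers are unique within a chain.
    """

    names: np.ndarray
    res_names: np.ndarray
    res_ids: np.ndarray
    chains: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    charges: np.ndarray | None = None
    radii: np.ndarray | None = None
    backbone: np.ndarray | None = None
    segment: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.coords)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError("coords must be (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        for name in ("names", "res_names", "chains", "elements"):
            arr = np.asarray(getattr(self, name), dtype=str)
            if arr.shape != (n,):
                raise StructureError(f"{name} must have length {n}")
            setattr(self, name, arr)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        if self.res_ids.shape != (n,):
            raise StructureError("res_ids must have length n")
        for name in ("charges", "radii"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (n,):
                    raise StructureError(f"{name} must have length {n}")
                setattr(self, name, arr)
        if self.backbone is None:
            self.backbone = np.zeros(n, dtype=bool)
        else:
            self.backbone = np.asarray(self.backbone, dtype=bool)
        if self.segment is not None:
            self.segment = np.asarray(self.segment, dtype=int)

    def __len__(self) -> int:
        return len(self.coords)

    # -- geometry ---------------------------------------------------------

    def com(self) -> np.ndarray:
        """Uniform-mass centre of the atom coordinates."""
        return self.coords.mean(axis=0)

    def translated(self, vector) -> "AtomicStructure":
        out = self.copy()
        out.coords = out.coords + np.asarray(vector, dtype=float)
        return out

    def transformed(self, rotation, translation) -> "AtomicStructure":
        out = self.copy()
        out.coords = out.coords @ np.asarray(rotation).T + np.asarray(
            translation
        )
        return out

    def with_coords(self, coords) -> "AtomicStructure":
        out = self.copy()
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.coords.shape:
            raise StructureError("coordinate shape mismatch")
        out.coords = coords
        return out

    # -- selection / assembly --------------------------------------------

    def select(self, mask) -> "AtomicStructure":
        mask = np.asarray(mask)
        return AtomicStructure(
            names=self.names[mask],
            res_names=self.res_names[mask],
            res_ids=self.res_ids[mask],
            chains=self.chains[mask],
            elements=self.elements[mask],
            coords=self.coords[mask],
            charges=None if self.charges is None else self.charges[mask],
            radii=None if self.radii is None else self.radii[mask],
            backbone=self.backbone[mask],
            segment=None if self.segment is None else self.segment[mask],
        )

    def select_chains(self, chains) -> "AtomicStructure":
        chains = set(chains)
        return self.select(np.isin(self.chains, sorted(chains)))

    def chain_mask(self, chains) -> np.ndarray:
        return np.isin(self.chains, sorted(set(chains)))

    @classmethod
    def concat(cls, parts) -> "AtomicStructure":
        parts = list(parts)
        if not parts:
            raise StructureError("nothing to concatenate")

        def cat(attr):
            vals = [getattr(p, attr) for p in parts]
            if any(v is None for v in vals):
                return None
            return np.concatenate(vals)

        return cls(
            names=cat("names"),
            res_names=cat("res_names"),
            res_ids=cat("res_ids"),
            chains=cat("chains"),
            elements=cat("elements"),
            coords=cat("coords"),
            charges=cat("charges"),
            radii=cat("radii"),
            backbone=cat("backbone"),
            segment=cat("segment"),
        )

    def relabeled(self, chain: str | None = None,
                  segment: int | None = None) -> "AtomicStructure":
        out = self.copy()
        if chain is not None:
            out.chains = np.full(len(out), chain, dtype="U4")
        if segment is not None:
            out.segment = np.full(len(out), segment, dtype=int)
        return out

    def copy(self) -> "AtomicStructure":
        return AtomicStructure(
            names=self.names.copy(),
            res_names=self.res_names.copy(),
            res_ids=self.res_ids.copy(),
            chains=self.chains.copy(),
            elements=self.elements.copy(),
            coords=self.coords.copy(),
            charges=None if self.charges is None else self.charges.copy(),
            radii=None if self.radii is None else self.radii.copy(),
            backbone=self.backbone.copy(),
            segment=None if self.segment is None else self.segment.copy(),
        )
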