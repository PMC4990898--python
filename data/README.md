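# Reference data

External database records are not redistributed with the package.
The sequence-identity check in `tests/test_acceptance.py` expects, when
available:

- `alpha_tubulin_bovine.fasta` — the bovine alpha-tubulin template chain
  sequence (PDB 1JFF, chain A)
- `alpha_tubulin_foram.fasta`  — the foram (Reticulomyxa filosa)
  alpha-tubulin sequence (EMBL CAA65329)

Place single-record FASTA files at those paths and re-run the suite to
compute the bovine-vs-foram identity. All other tests and the acceptance
script are self-contained.
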