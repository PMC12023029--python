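"""Reference sequences and residue bookkeeping.

All residue indices in this package are 1-based and ranges are inclusive,
matching the conventions of the structural-biology literature on
alpha-synuclein (aSyn).
"""

from __future__ import annotations

# Canonical human alpha-synuclein (UniProt P37840), 140 residues.
ASYN_SEQUENCE = (
    "MDVFMKGLSKAKEGVVAAAEKTKQGVAEAAGKTKEGVLYVGSKTKEGVVH"
    "GVATVAEKTKEQVTNVGGAVVTGVTAVAQKTVEGAGSIAAATGFVKKDQL"
    "GKNEEGAPQEGILEDMPVDPDNEAYEMPSEEGYQDYEPEA"
)

# Bradykinin: the unstructured reference peptide used to factor
# condition-dependent chemical-exchange rates out of HDX data.
BRADYKININ_SEQUENCE = "RPPGFSPFR"

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# Average residue mass used for coarse Calpha beads (Da).
MEAN_RESIDUE_MASS = 110.0


def validate_sequence(sequence: str) -> str:
    """Return ``sequence`` upper-cased, raising ``ValueError`` on bad letters."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = sequence.upper()
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"invalid residue letter(s): {sorted(bad)}")
    return seq


def acidic_residues(sequence: str, start: int = 1, end: int | None = None) -> list[int]:
    """1-based positions of Asp/Glu within ``[start, end]`` (inclusive)."""
    seq = validate_sequence(sequence)
    if end is None:
        end = len(seq)
    return [i for i in range(start, end + 1) if seq[i - 1] in "DE"]
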