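"""In-silico peptide chemistry: tryptic digestion and monoisotopic mass.

Masses are neutral (uncharged) monoisotopic masses in daltons; charge is
carried elsewhere only as an identification-filter attribute.
"""

from __future__ import annotations

# Standard monoisotopic residue masses (Da) for the 20 canonical amino acids.
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146372,
    "A": 71.03711379,
    "S": 87.03202841,
    "P": 97.05276385,
    "V": 99.06841391,
    "T": 101.04767847,
    "C": 103.00918448,
    "L": 113.08406398,
    "I": 113.08406398,
    "N": 114.04292744,
    "D": 115.02694302,
    "Q": 128.05857751,
    "K": 128.09496302,
    "E": 129.04259309,
    "M": 131.04048509,
    "H": 137.05891186,
    "F": 147.06841391,
    "R": 156.10111102,
    "Y": 163.06332853,
    "W": 186.07931295,
}

WATER_MONO = 18.0105646863

STANDARD_RESIDUES = frozenset(MONOISOTOPIC_RESIDUE_MASS)


def validate_sequence(sequence: str) -> None:
    """Raise ``ValueError`` (reporting the position) on a non-standard residue."""
    for i, aa in enumerate(sequence):
        if aa not in STANDARD_RESIDUES:
            raise ValueError(
                f"invalid residue {aa!r} at position {i} in sequence {sequence[:30]!r}"
            )


def peptide_mass(sequence: str) -> float:
    """Neutral monoisotopic mass of a peptide: residue masses plus one water."""
    if not sequence:
        raise ValueError("empty sequence has no defined mass")
    validate_sequence(sequence)
    return sum(MONOISOTOPIC_RESIDUE_MASS[aa] for aa in sequence) + WATER_MONO


def digest(sequence: str, max_missed: int = 0) -> list[str]:
    """Tryptic digest: cleave C-terminal to K or R unless followed by P.

    Returns every peptide with at most ``max_missed`` internal missed
    cleavages, ordered by missed-cleavage count and then by position.  The
    0-missed peptides concatenate back to the input sequence.
    """
    validate_sequence(sequence)
    if not sequence:
        return []
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    # Cleavage boundaries (index = position after which we cut).
    cuts = [0]
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and sequence[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(sequence))
    peptides: list[str] = []
    for missed in range(max_missed + 1):
        for j in range(len(cuts) - 1 - missed):
            peptides.append(sequence[cuts[j] : cuts[j + 1 + missed]])
    return peptides
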