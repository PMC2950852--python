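"""Heuristic annotation of bipartite plastid-targeting presequences.

Nucleus-encoded proteins of diatom complex plastids carry an N-terminal
bipartite presequence: a hydrophobic signal peptide (SP) ending at an
A-down-F cleavage site within an ASAF/AFAP-like motif (with a conserved
proline two residues after the phenylalanine), followed by a
serine/threonine-rich transit peptide (TP).  This module annotates those
features with explicit, configurable rules — hydrophobicity, cleavage
motif, ST-richness — rather than trained predictors, so every call is
auditable.  All reported coordinates are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .codon_compare import align_pair_protein
from .seq_io import GAP

#: Kyte-Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass
class SignalPeptideConfig:
    """Rules for the SP scan; defaults bracket observed diatom SPs."""

    min_len: int = 12
    max_len: int = 30
    hydrophobicity_threshold: float = 1.6
    window: int = 7
    f_bonus: float = 1.0
    p_bonus: float = 1.0


@dataclass
class CleavageCandidate:
    """A candidate SP cleavage boundary after residue ``position`` (1-based)."""

    position: int
    mean_hydrophobicity: float
    has_f_after: bool
    has_p_plus3: bool
    motif_score: float


@dataclass
class PresequenceAnnotation:
    sp_span: tuple[int, int] | None  # 1-based inclusive
    cleavage_site: int | None  # boundary after this residue
    cleavage_motif: str | None  # residues at positions -1..+3 around boundary
    sp_mean_hydrophobicity: float | None
    tp_span: tuple[int, int] | None
    tp_st_fraction: float | None
    tp_net_charge: int | None
    verdict: str  # bipartite | sp_only | none
    extra_n_terminal_length: int | None = None
    candidates: list[CleavageCandidate] = field(default_factory=list)


def mean_hydrophobicity(segment: str, scale: dict[str, float] | None = None) -> float:
    scale = scale or KYTE_DOOLITTLE
    values = [scale[a] for a in segment.upper() if a in scale]
    if not values:
        raise ValueError("no scorable residues in segment")
    return sum(values) / len(values)


def scan_signal_peptide(
    protein: str, config: SignalPeptideConfig | None = None
) -> list[CleavageCandidate]:
    """Rank candidate SP cleavage boundaries.

    A boundary after residue i (1-based, i in [min_len, max_len]) is a
    candidate when the mean Kyte-Doolittle hydrophobicity of residues
    2..i exceeds the threshold and residue i is alanine (the small
    residue at -1 of the cleavage consensus).  Candidates are ranked by a
    motif score: bonuses for phenylalanine at +1 and proline at +3, then
    by hydrophobicity, then by shorter SP.
    """
    config = config or SignalPeptideConfig()
    protein = protein.upper()
    candidates = []
    for i in range(config.min_len, min(config.max_len, len(protein) - 1) + 1):
        if protein[i - 1] != "A":
            continue
        h = mean_hydrophobicity(protein[1:i])
        if h <= config.hydrophobicity_threshold:
            continue
        has_f = i < len(protein) and protein[i] == "F"
        has_p = i + 2 < len(protein) and protein[i + 2] == "P"
        score = config.f_bonus * has_f + config.p_bonus * has_p
        candidates.append(
            CleavageCandidate(
                position=i,
                mean_hydrophobicity=h,
                has_f_after=has_f,
                has_p_plus3=has_p,
                motif_score=score,
            )
        )
    candidates.sort(key=lambda c: (-c.motif_score, -c.mean_hydrophobicity, c.position))
    return candidates


def score_transit_peptide(protein: str, tp_span: tuple[int, int]) -> tuple[float, int]:
    """ST fraction and net charge (#KR - #DE) of the TP span (1-based incl.)."""
    start, end = tp_span
    if not (1 <= start <= end <= len(protein)):
        raise ValueError(f"span {tp_span} outside protein of length {len(protein)}")
    segment = protein[start - 1 : end].upper()
    st = sum(a in "ST" for a in segment)
    charge = sum(a in "KR" for a in segment) - sum(a in "DE" for a in segment)
    return st / len(segment), charge


def extra_n_terminal_length(protein: str, mature_reference: str) -> int:
    """Length of the N-terminal extension relative to a mature homologue.

    Aligns the two proteins globally and counts query residues before the
    first column where the mature reference is present.
    """
    pa = align_pair_protein(protein, mature_reference, ids=("query", "mature"))
    q_row, m_row = pa.rows
    extra = 0
    for q, m in zip(q_row, m_row):
        if m != GAP:
            break
        if q != GAP:
            extra += 1
    return extra


def annotate_presequence(
    protein: str,
    mature_reference: str | None = None,
    sp_config: SignalPeptideConfig | None = None,
    tp_window: int = 15,
    tp_st_cutoff: float = 0.20,
) -> PresequenceAnnotation:
    """Full bipartite-presequence annotation.

    The best SP candidate fixes the cleavage site; the TP is scored over
    the ``tp_window`` residues that follow.  ``verdict`` is ``bipartite``
    when an SP is found and the TP ST-fraction reaches ``tp_st_cutoff``,
    ``sp_only`` when only the SP criterion holds, else ``none``.
    """
    protein = protein.upper()
    candidates = scan_signal_peptide(protein, sp_config)
    extra = (
        extra_n_terminal_length(protein, mature_reference)
        if mature_reference is not None
        else None
    )
    if not candidates:
        return PresequenceAnnotation(
            sp_span=None, cleavage_site=None, cleavage_motif=None,
            sp_mean_hydrophobicity=None, tp_span=None, tp_st_fraction=None,
            tp_net_charge=None, verdict="none", extra_n_terminal_length=extra,
        )
    best = candidates[0]
    i = best.position
    motif = protein[i - 1 : i + 3]
    tp_end = min(i + tp_window, len(protein))
    tp_span = (i + 1, tp_end)
    st_fraction, charge = score_transit_peptide(protein, tp_span)
    verdict = "bipartite" if st_fraction >= tp_st_cutoff else "sp_only"
    return PresequenceAnnotation(
        sp_span=(1, i),
        cleavage_site=i,
        cleavage_motif=motif,
        sp_mean_hydrophobicity=best.mean_hydrophobicity,
        tp_span=tp_span,
        tp_st_fraction=st_fraction,
        tp_net_charge=charge,
        verdict=verdict,
        extra_n_terminal_length=extra,
        candidates=candidates,
    )
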