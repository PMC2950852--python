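"""Compositional and divergence statistics for homologous coding genes.

The central diagnostic for a recently transferred gene is compositional:
plastid genomes drift AT-rich, nuclear genomes GC-rich, and selection on
the protein leaves synonymous sites free to record that mutational
pressure.  Restricting attention to codon pairs that differ by exactly one
synonymous change and tabulating which nucleotide each genome carries at
the mutated site therefore reads out the compartment-specific pressure
directly, and a gene that moved compartments recently sits between the two
regimes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .seq_io import (
    GAP,
    IUPAC_NT,
    CodingGene,
    CodonAlignment,
    GeneticCode,
    ProteinAlignment,
    BACTERIAL_CODE,
    translate,
)

UNAMBIGUOUS = set("ACGT")


def at_content(seq: str) -> float:
    """(A+T) / (A+C+G+T), case-insensitive; ambiguity codes excluded."""
    seq = seq.upper().replace("U", "T")
    counts = {nt: seq.count(nt) for nt in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("no unambiguous nucleotides in sequence")
    return (counts["A"] + counts["T"]) / denom


def composition_profile(genes: list[CodingGene]) -> pd.DataFrame:
    """Per-gene nucleotide counts and AT fraction (whole CDS)."""
    rows = []
    for g in genes:
        seq = g.cds
        counts = {nt: seq.count(nt) for nt in "ACGT"}
        denom = sum(counts.values())
        rows.append(
            {
                "id": g.id,
                "taxon": g.taxon,
                "compartment": g.compartment,
                "group": g.group,
                **{f"n_{nt}": counts[nt] for nt in "ACGT"},
                "length": len(seq),
                "at_fraction": (counts["A"] + counts["T"]) / denom,
            }
        )
    return pd.DataFrame(rows)


def group_composition(profile: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean AT fraction per (group, compartment)."""
    return (
        profile.groupby(["group", "compartment"], as_index=False)
        .agg(n_genes=("id", "size"), mean_at_fraction=("at_fraction", "mean"))
        .sort_values(["group", "compartment"], ignore_index=True)
    )


# ---------------------------------------------------------------------------
# codon-pair classification


def classify_codon_pair(c1: str, c2: str, code: GeneticCode = BACTERIAL_CODE) -> str:
    """Classify a sense-codon pair.

    Returns one of ``identical``, ``synonymous_single`` (same amino acid,
    one differing position), ``synonymous_multi`` (same amino acid, >1
    differing positions) or ``nonsynonymous``.
    """
    c1, c2 = c1.upper(), c2.upper()
    for c in (c1, c2):
        if c not in code.codon_to_aa:
            raise ValueError(f"ambiguous or illegal codon {c!r}")
        if code.codon_to_aa[c] == "*":
            raise ValueError(f"stop codon {c!r} is not a sense codon")
    if c1 == c2:
        return "identical"
    if code.codon_to_aa[c1] != code.codon_to_aa[c2]:
        return "nonsynonymous"
    n_diff = sum(a != b for a, b in zip(c1, c2))
    return "synonymous_single" if n_diff == 1 else "synonymous_multi"


# ---------------------------------------------------------------------------
# synonymous-mutated-site composition


@dataclass
class SynonymousSiteTable:
    """Single-position synonymous codon differences and their composition.

    ``records`` holds one row per (gene pair, codon column) classified
    ``synonymous_single``: the two codons, the mutated position within the
    codon (1..3) and the nucleotide each gene carries there.  ``by_category``
    aggregates, per category label, the nucleotide carried by genes of that
    category at the mutated sites.  Aggregates are pooled across all pairs
    within the comparison design.
    """

    records: pd.DataFrame
    by_category: pd.DataFrame

    @property
    def n_records(self) -> int:
        return len(self.records)

    def at_fraction(self, category: str) -> float:
        row = self.by_category.set_index("category").loc[category]
        return float(row["at_fraction_at_mutated_sites"])


_RECORD_COLUMNS = [
    "gene_1", "gene_2", "category_1", "category_2", "codon_column",
    "codon_1", "codon_2", "mutated_position", "nt_1", "nt_2",
]


def synonymous_site_composition(
    ca: CodonAlignment,
    categories: dict[str, str],
    code: GeneticCode = BACTERIAL_CODE,
    pairs: list[tuple[str, str]] | None = None,
) -> SynonymousSiteTable:
    """Tabulate mutated-site nucleotides over synonymous single-hit codons.

    ``categories`` labels every gene (e.g. its compartment or group); the
    per-category aggregate counts the nucleotide carried *by that
    category's gene* at each mutated site.  ``pairs`` restricts the
    comparison design; default is all unordered gene pairs.
    """
    missing = set(ca.ids) - set(categories)
    if missing:
        raise ValueError(f"categories missing for genes {sorted(missing)}")
    if pairs is None:
        pairs = list(itertools.combinations(ca.ids, 2))
    records = []
    for g1, g2 in pairs:
        row1, row2 = ca.row(g1), ca.row(g2)
        for j, (c1, c2) in enumerate(zip(row1, row2)):
            if c1 == "---" or c2 == "---":
                continue
            if set(c1) - UNAMBIGUOUS or set(c2) - UNAMBIGUOUS:
                continue  # ambiguity codes excluded from all denominators
            if classify_codon_pair(c1, c2, code) != "synonymous_single":
                continue
            pos = next(k for k in range(3) if c1[k] != c2[k])
            records.append(
                dict(
                    zip(
                        _RECORD_COLUMNS,
                        [g1, g2, categories[g1], categories[g2], j,
                         c1, c2, pos + 1, c1[pos], c2[pos]],
                    )
                )
            )
    records_df = pd.DataFrame(records, columns=_RECORD_COLUMNS)
    if records_df.empty:
        warnings.warn("no synonymous single-position codon differences found")
    by_category = _aggregate_by_category(records_df, sorted(set(categories.values())))
    return SynonymousSiteTable(records=records_df, by_category=by_category)


def _aggregate_by_category(records: pd.DataFrame, labels: list[str]) -> pd.DataFrame:
    rows = []
    for label in labels:
        counts = {nt: 0 for nt in "ACGT"}
        for side in (1, 2):
            sub = records[records[f"category_{side}"] == label]
            for nt, n in sub[f"nt_{side}"].value_counts().items():
                counts[nt] += int(n)
        total = sum(counts.values())
        rows.append(
            {
                "category": label,
                **{f"n_{nt}": counts[nt] for nt in "ACGT"},
                "n_sites": total,
                "at_fraction_at_mutated_sites": (
                    (counts["A"] + counts["T"]) / total if total else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pairwise divergence


@dataclass
class DivergenceReport:
    """Nucleotide and protein divergence between two aligned homologues."""

    gene_1: str
    gene_2: str
    aligned_length: int
    substituted: int
    substitution_fraction: float
    protein_identity: float | None = None
    protein_similarity: float | None = None
    similarity_matrix: str = "BLOSUM62"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def pairwise_nucleotide_divergence(
    g1: CodingGene, g2: CodingGene, via: ProteinAlignment
) -> DivergenceReport:
    """Count substituted nucleotides over both-ungapped codon columns.

    ``via`` must be a pairwise protein alignment of exactly the two genes;
    its gap pattern defines nucleotide homology via back-alignment.
    """
    from .seq_io import back_align

    if set(via.ids) != {g1.id, g2.id}:
        raise ValueError("alignment ids do not match the two genes")
    ca = back_align(via, [g1, g2])
    row1, row2 = ca.row(g1.id), ca.row(g2.id)
    aligned = substituted = 0
    for c1, c2 in zip(row1, row2):
        if c1 == "---" or c2 == "---":
            continue
        for a, b in zip(c1, c2):
            if a not in UNAMBIGUOUS or b not in UNAMBIGUOUS:
                continue
            aligned += 1
            substituted += a != b
    if aligned == 0:
        raise ValueError(f"{g1.id}/{g2.id}: zero aligned nucleotide overlap")
    identity, similarity = protein_identity_similarity(
        via.rows[0], via.rows[1]
    )
    return DivergenceReport(
        gene_1=g1.id,
        gene_2=g2.id,
        aligned_length=aligned,
        substituted=substituted,
        substitution_fraction=substituted / aligned,
        protein_identity=identity,
        protein_similarity=similarity,
    )


def protein_identity_similarity(
    a1: str, a2: str, matrix_name: str = "BLOSUM62"
) -> tuple[float, float]:
    """Identity and similarity fractions over both-ungapped columns.

    Similarity counts columns whose substitution score is positive
    (identities included) — the "positives" convention.
    """
    if len(a1) != len(a2):
        raise ValueError("aligned strings differ in length")
    matrix = substitution_matrices.load(matrix_name)
    n = ident = similar = 0
    for x, y in zip(a1.upper(), a2.upper()):
        if x == GAP or y == GAP:
            continue
        n += 1
        if x == y:
            ident += 1
        if x in matrix.alphabet and y in matrix.alphabet and matrix[x, y] > 0:
            similar += 1
    if n == 0:
        raise ValueError("no both-ungapped columns")
    return ident / n, similar / n


def align_pair_protein(
    a1: str,
    a2: str,
    ids: tuple[str, str] = ("seq1", "seq2"),
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> ProteinAlignment:
    """Optimal global pairwise protein alignment (affine gap penalties).

    Deterministic: of co-optimal alignments the first in the aligner's
    enumeration order is returned.
    """
    if not a1 or not a2:
        raise ValueError("empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.mode = "global"
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    alignment = aligner.align(a1.upper(), a2.upper())[0]
    rows = [str(alignment[0]), str(alignment[1])]
    return ProteinAlignment(ids=list(ids), rows=rows)


def alignment_score(
    a1: str,
    a2: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> float:
    """Score of the optimal global alignment under the same parameters."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.mode = "global"
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return float(aligner.score(a1.upper(), a2.upper()))


# ---------------------------------------------------------------------------
# intermediacy


@dataclass
class IntermediacyReport:
    focal_id: str
    focal_at: float
    plastid_mean: float
    reference_nuclear_mean: float
    intermediate: bool


def intermediacy_rank(
    profile: pd.DataFrame,
    focal_ids: list[str],
    plastid_compartment: str = "plastid",
    reference_query: str = "compartment == 'nuclear'",
) -> list[IntermediacyReport]:
    """Test whether focal genes' AT fractions sit strictly between regimes.

    The plastid endpoint is the mean AT fraction of all plastid genes; the
    nuclear endpoint is the mean over ``reference_query`` rows excluding
    the focal genes themselves (for a transferred gene, the long-resident
    nuclear homologues).  Strict inequalities: a focal gene equal to an
    endpoint is not intermediate.
    """
    plastid = profile[profile["compartment"] == plastid_compartment]
    reference = profile.query(reference_query)
    reference = reference[~reference["id"].isin(focal_ids)]
    if plastid.empty or reference.empty:
        raise ValueError("missing plastid or reference-nuclear category")
    p_mean = float(plastid["at_fraction"].mean())
    n_mean = float(reference["at_fraction"].mean())
    lo, hi = sorted([p_mean, n_mean])
    reports = []
    for fid in focal_ids:
        rows = profile[profile["id"] == fid]
        if rows.empty:
            raise ValueError(f"focal gene {fid!r} not in profile")
        at = float(rows["at_fraction"].iloc[0])
        reports.append(
            IntermediacyReport(
                focal_id=fid,
                focal_at=at,
                plastid_mean=p_mean,
                reference_nuclear_mean=n_mean,
                intermediate=lo < at < hi,
            )
        )
    return reports
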