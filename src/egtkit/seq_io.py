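"""Sequence, alignment and metadata I/O plus codon-level plumbing.

Coding sequences arrive as nucleotide FASTA with a sidecar metadata table
(taxon, genomic compartment, group, translation table).  Composition and
divergence statistics downstream all operate on a codon alignment obtained
by threading each CDS back through its protein alignment, so this module
owns translation, back-alignment, column masking and third-position
removal.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NT_SYMBOLS = set("ACGTUNRYSWKMBDHV-")
AA_SYMBOLS = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*-")
GAP = "-"

#: IUPAC ambiguity code -> set of unambiguous nucleotides
IUPAC_NT = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

COMPARTMENTS = ("plastid", "nuclear", "cyanobacterial")


class SequenceParseError(ValueError):
    """Raised when a FASTA record is malformed or contains illegal symbols."""


class TranslationError(ValueError):
    """Raised on internal stop codons or CDS/protein inconsistencies."""


# ---------------------------------------------------------------------------
# genetic codes


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table as a total map over the 64 codons.

    ``codon_to_aa`` maps every unambiguous codon to a one-letter amino
    acid, with ``*`` for stops.  Table 1 (standard) and table 11
    (bacterial/plastid) share all 64 codon assignments and differ only in
    their start-codon sets, which are irrelevant here.
    """

    table_id: int
    codon_to_aa: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(f"genetic code must cover 64 codons, got {len(self.codon_to_aa)}")

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa.get(codon.upper()) == "*"


def genetic_code(table_id: int) -> GeneticCode:
    """Load an NCBI translation table (by number) as a :class:`GeneticCode`."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return GeneticCode(table_id=table_id, codon_to_aa=mapping)


STANDARD_CODE = genetic_code(1)
BACTERIAL_CODE = genetic_code(11)


def default_code_for_compartment(compartment: str) -> GeneticCode:
    # plastid and cyanobacterial CDS use the bacterial-style table 11
    return STANDARD_CODE if compartment == "nuclear" else BACTERIAL_CODE


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CodingGene:
    """A nucleotide CDS with its taxon/compartment metadata."""

    id: str
    taxon: str
    compartment: str
    group: str
    cds: str
    genetic_code_id: int = 11

    def __post_init__(self) -> None:
        object.__setattr__(self, "cds", self.cds.upper().replace("U", "T"))
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"{self.id}: unknown compartment {self.compartment!r}")
        if len(self.cds) % 3:
            raise ValueError(f"{self.id}: CDS length {len(self.cds)} not divisible by 3")
        bad = set(self.cds) - set(IUPAC_NT)
        if bad:
            raise ValueError(f"{self.id}: non-IUPAC symbols {sorted(bad)}")
        code = genetic_code(self.genetic_code_id)
        for i in range(0, len(self.cds) - 3, 3):
            if code.is_stop(self.cds[i : i + 3]):
                raise ValueError(f"{self.id}: internal stop codon at nucleotide {i + 1}")

    @property
    def code(self) -> GeneticCode:
        return genetic_code(self.genetic_code_id)

    @property
    def codons(self) -> list[str]:
        cds = self.cds
        return [cds[i : i + 3] for i in range(0, len(cds), 3)]

    @property
    def protein(self) -> str:
        return translate(self.cds, self.code)


@dataclass
class MaskPolicy:
    """Column-exclusion rules applied to a protein alignment.

    The default drops any column containing a gap or an X, the strictest
    reproducible reading of excluding gaps and ambiguously aligned
    regions.  ``max_entropy`` (bits) optionally also drops high-entropy
    columns as ambiguously aligned.
    """

    drop_gap: bool = True
    drop_x: bool = True
    max_entropy: float | None = None


@dataclass
class ProteinAlignment:
    """Equal-length gapped amino-acid rows with a per-column keep mask."""

    ids: list[str]
    rows: list[str]
    column_mask: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")
        if not self.column_mask:
            self.column_mask = [True] * self.n_columns
        if len(self.column_mask) != self.n_columns:
            raise ValueError("column_mask length does not match alignment length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, gene_id: str) -> str:
        return self.rows[self.ids.index(gene_id)]

    def kept_columns(self) -> list[int]:
        return [j for j, keep in enumerate(self.column_mask) if keep]

    def masked_rows(self) -> list[str]:
        """Rows restricted to kept columns."""
        kept = self.kept_columns()
        return ["".join(row[j] for j in kept) for row in self.rows]


@dataclass
class CodonAlignment:
    """Codon-resolution alignment derived from a protein alignment.

    Each cell is either a 3-nt codon or ``---``; ungapping any row
    reproduces the source CDS, and every non-gap cell translates to the
    residue at the homologous protein column.
    """

    ids: list[str]
    codon_rows: list[list[str]]
    source: ProteinAlignment | None = None

    @property
    def n_columns(self) -> int:
        return len(self.codon_rows[0]) if self.codon_rows else 0

    def row(self, gene_id: str) -> list[str]:
        return self.codon_rows[self.ids.index(gene_id)]

    def ungapped_cds(self, gene_id: str) -> str:
        return "".join(c for c in self.row(gene_id) if c != "---")


# ---------------------------------------------------------------------------
# FASTA and tables


def read_fasta(path: str | Path | io.TextIOBase, alphabet: str = "nt") -> list[tuple[str, str]]:
    """Read FASTA records, validating symbols against ``alphabet`` (nt|aa).

    Order is preserved, sequences are upper-cased, and gap characters are
    retained so aligned FASTA round-trips.
    """
    allowed = NT_SYMBOLS if alphabet == "nt" else AA_SYMBOLS
    records = []
    for rec in SeqIO.parse(path if isinstance(path, io.TextIOBase) else str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - allowed
        if bad:
            raise SequenceParseError(
                f"record {rec.id!r}: illegal {alphabet} symbols {sorted(bad)}"
            )
        records.append((rec.id, seq))
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    seqrecs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the gene metadata TSV (id, taxon, compartment, group, genetic_code_id)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "taxon": str})
    required = {"id", "taxon", "compartment", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns {sorted(missing)}")
    if "genetic_code_id" not in df.columns:
        df["genetic_code_id"] = [
            11 if c != "nuclear" else 1 for c in df["compartment"]
        ]
    return df


def load_genes(fasta_path: str | Path, metadata_path: str | Path) -> list[CodingGene]:
    """Join a nucleotide FASTA with its metadata table into CodingGene objects."""
    meta = read_metadata(metadata_path).set_index("id")
    genes = []
    for name, seq in read_fasta(fasta_path, "nt"):
        if name not in meta.index:
            raise ValueError(f"sequence {name!r} missing from metadata")
        row = meta.loc[name]
        genes.append(
            CodingGene(
                id=name,
                taxon=str(row["taxon"]),
                compartment=str(row["compartment"]),
                group=str(row["group"]),
                cds=seq,
                genetic_code_id=int(row["genetic_code_id"]),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# translation and codon alignment


def translate(cds: str, code: GeneticCode = BACTERIAL_CODE) -> str:
    """Translate a CDS, dropping a trailing stop; internal stops are errors.

    Ambiguous codons translate to the unique residue shared by all their
    expansions, else ``X``.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3:
        raise TranslationError(f"CDS length {len(cds)} not divisible by 3")
    residues = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        aa = _translate_codon(codon, code)
        if aa == "*":
            if i == n_codons - 1:
                break  # trailing stop dropped
            raise TranslationError(f"internal stop codon {codon} at codon {i + 1}")
        residues.append(aa)
    return "".join(residues)


def _translate_codon(codon: str, code: GeneticCode) -> str:
    if codon in code.codon_to_aa:
        return code.codon_to_aa[codon]
    try:
        expansions = {
            code.codon_to_aa[a + b + c]
            for a in IUPAC_NT[codon[0]]
            for b in IUPAC_NT[codon[1]]
            for c in IUPAC_NT[codon[2]]
        }
    except KeyError as exc:
        raise TranslationError(f"illegal codon {codon!r}") from exc
    return expansions.pop() if len(expansions) == 1 else "X"


def back_align(pa: ProteinAlignment, genes: Sequence[CodingGene]) -> CodonAlignment:
    """Thread each gene's CDS through its gapped protein row.

    Every gene's translation must equal its ungapped protein row;
    mismatches are reported with the gene id and residue index (1-based).
    """
    by_id = {g.id: g for g in genes}
    missing = set(pa.ids) - set(by_id)
    if missing:
        raise ValueError(f"genes missing for alignment rows {sorted(missing)}")
    codon_rows = []
    for gene_id, row in zip(pa.ids, pa.rows):
        gene = by_id[gene_id]
        codons = gene.codons
        if codons and gene.code.is_stop(codons[-1]):
            codons = codons[:-1]
        ungapped = row.replace(GAP, "")
        if len(ungapped) != len(codons):
            raise TranslationError(
                f"{gene_id}: protein row has {len(ungapped)} residues "
                f"but CDS encodes {len(codons)}"
            )
        cells, k = [], 0
        for residue in row:
            if residue == GAP:
                cells.append("---")
                continue
            codon = codons[k]
            aa = _translate_codon(codon, gene.code)
            if aa != residue:
                raise TranslationError(
                    f"{gene_id}: codon {codon} translates to {aa!r}, "
                    f"protein row has {residue!r} at residue {k + 1}"
                )
            cells.append(codon)
            k += 1
        codon_rows.append(cells)
    return CodonAlignment(ids=list(pa.ids), codon_rows=codon_rows, source=pa)


# ---------------------------------------------------------------------------
# masking


def _column_entropy(column: str) -> float:
    import math

    counts: dict[str, int] = {}
    for ch in column:
        counts[ch] = counts.get(ch, 0) + 1
    n = len(column)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def mask_columns(pa: ProteinAlignment, policy: MaskPolicy | None = None) -> ProteinAlignment:
    """Flag alignment columns excluded from downstream statistics."""
    policy = policy or MaskPolicy()
    mask = []
    for j in range(pa.n_columns):
        column = "".join(row[j] for row in pa.rows)
        keep = True
        if set(column) == {GAP}:
            keep = False
        if policy.drop_gap and GAP in column:
            keep = False
        if policy.drop_x and "X" in column:
            keep = False
        if keep and policy.max_entropy is not None:
            if _column_entropy(column) > policy.max_entropy:
                keep = False
        mask.append(keep)
    return ProteinAlignment(ids=list(pa.ids), rows=list(pa.rows), column_mask=mask)


def apply_mask(ca: CodonAlignment) -> CodonAlignment:
    """Restrict a codon alignment to its source alignment's kept columns."""
    if ca.source is None:
        return ca
    kept = ca.source.kept_columns()
    rows = [[row[j] for j in kept] for row in ca.codon_rows]
    return CodonAlignment(ids=list(ca.ids), codon_rows=rows, source=None)


def drop_third_positions(ca: CodonAlignment) -> list[tuple[str, str]]:
    """First+second codon positions only, as a nucleotide alignment.

    Third positions are the saturated ones under strong AT/GC pressure;
    excluding them is the standard guard before nucleotide tree building.
    Gap cells become two gap characters so columns stay homologous.
    """
    out = []
    for gene_id, row in zip(ca.ids, ca.codon_rows):
        seq = "".join("--" if c == "---" else c[:2] for c in row)
        out.append((gene_id, seq))
    return out


# ---------------------------------------------------------------------------
# trees


def read_newick(path: str | Path):
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def write_newick(tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
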