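"""Synthetic coding-gene evolution with compartment-specific AT/GC bias
and a duplication-plus-transfer event.

The generator evolves a single-copy coding gene along a known tree.
Mutations are proposed one nucleotide at a time and pass through a
selection/mutation-bias filter: proposals creating stop codons are
rejected; synonymous proposals are accepted with a probability tilted
toward the lineage compartment's target AT content at synonymous sites
(AT-increasing changes accepted with probability ``at_bias``,
GC-increasing with ``1 - at_bias``); nonsynonymous proposals face the
same compositional tilt further thinned by ``p_nonsyn_accept``
(purifying selection).  Branch lengths are expected *accepted*
substitutions per codon.

An endosymbiotic-transfer event duplicates the gene part-way along a
chosen branch: the copy switches compartment (hence bias regime), evolves
independently to the present, and optionally gains a bipartite targeting
presequence.  The grafted true tree, per-gene compartments, the full
mutation log and any planted presequence coordinates are returned as
ground truth, so every analysis module can be scored against what
actually happened.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .seq_io import CodingGene, GeneticCode, ProteinAlignment, genetic_code, translate  # noqa: F401 (translate re-exported for callers)

NT = "ACGT"
AT = {"A", "T"}


@dataclass
class EgtEvent:
    """Duplication + transfer on the branch above ``branch`` (a node label),
    at ``time_fraction`` of the branch measured from its parent."""

    branch: str
    time_fraction: float
    new_compartment: str
    new_name: str = "transferred"


@dataclass
class PresequenceInsert:
    """SP + TP amino-acid template prepended to the transferred copy."""

    signal_peptide: str = "MKLSLLLLGAVAA"
    transit_peptide: str = "FSPSATSSTRASSLPM"


@dataclass
class SimulationConfig:
    newick: str
    root_cds_length: int = 120  # codons
    compartments: dict[str, str] = field(default_factory=dict)  # node label -> compartment
    root_compartment: str = "plastid"
    at_bias: dict[str, float] = field(
        default_factory=lambda: {"plastid": 0.70, "nuclear": 0.45, "cyanobacterial": 0.55}
    )
    p_nonsyn_accept: float = 0.15
    egt_event: EgtEvent | None = None
    presequence_insert: PresequenceInsert | None = None
    genetic_code_id: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        for c, b in self.at_bias.items():
            if not 0.0 <= b <= 1.0:
                raise ValueError(f"at_bias[{c}] = {b} outside [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class TruthSet:
    tree: dendropy.Tree  # true tree incl. the transferred copy
    root_cds: str
    compartments: dict[str, str]  # per emitted gene
    mutation_log: pd.DataFrame  # edge, step, codon, position, from, to, synonymous
    transferred_id: str | None
    donor_id: str | None  # tip whose terminal branch hosted the event
    presequence: dict | None  # planted SP/TP coordinates on the transferred protein
    config: SimulationConfig


# ---------------------------------------------------------------------------
# helpers

_LOG_COLUMNS = ["edge", "step", "codon_index", "position", "from_nt", "to_nt", "synonymous"]


def _sense_codons(code: GeneticCode) -> list[str]:
    return sorted(c for c, aa in code.codon_to_aa.items() if aa != "*")


def _synonym_sets(code: GeneticCode) -> dict[str, list[str]]:
    by_aa: dict[str, list[str]] = {}
    for c in _sense_codons(code):
        by_aa.setdefault(code.codon_to_aa[c], []).append(c)
    return by_aa


def _random_root_cds(
    n_codons: int, code: GeneticCode, at3_target: float, rng: np.random.Generator
) -> str:
    """Random CDS: uniform amino acids, synonymous codon drawn with third
    positions weighted toward the root compartment's AT target."""
    by_aa = _synonym_sets(code)
    aas = sorted(by_aa)
    out = []
    for _ in range(n_codons):
        aa = aas[rng.integers(len(aas))]
        codons = by_aa[aa]
        weights = np.array(
            [at3_target if c[2] in AT else 1.0 - at3_target for c in codons]
        )
        weights = weights / weights.sum() if weights.sum() > 0 else None
        out.append(codons[rng.choice(len(codons), p=weights)])
    return "".join(out)


def _acceptance(
    old_codon: str,
    new_codon: str,
    pos: int,
    code: GeneticCode,
    at_bias: float,
    p_nonsyn: float,
) -> tuple[float, bool]:
    """(acceptance probability, synonymous flag) for a proposed change."""
    new_aa = code.codon_to_aa[new_codon]
    if new_aa == "*":
        return 0.0, False
    old_nt, new_nt = old_codon[pos], new_codon[pos]
    if (old_nt in AT) == (new_nt in AT):
        tilt = 0.5  # A<->T or G<->C: composition unchanged
    elif new_nt in AT:
        tilt = at_bias
    else:
        tilt = 1.0 - at_bias
    synonymous = new_aa == code.codon_to_aa[old_codon]
    if synonymous:
        return tilt, True
    return min(1.0, 2.0 * tilt * p_nonsyn), False


def _evolve_branch(
    cds: list[str],
    n_accept: int,
    code: GeneticCode,
    at_bias: float,
    p_nonsyn: float,
    rng: np.random.Generator,
    edge_label: str,
    log: list,
) -> None:
    """Accept exactly ``n_accept`` mutations in place, logging each."""
    n_codons = len(cds)
    accepted = 0
    budget = 400 * (n_accept + 10)  # guards unreachable-bias configurations
    while accepted < n_accept and budget > 0:
        budget -= 1
        ci = int(rng.integers(n_codons))
        pos = int(rng.integers(3))
        old = cds[ci]
        new_nt = NT[int(rng.integers(4))]
        if new_nt == old[pos]:
            continue
        new = old[:pos] + new_nt + old[pos + 1 :]
        p, synonymous = _acceptance(old, new, pos, code, at_bias, p_nonsyn)
        if rng.random() < p:
            cds[ci] = new
            log.append((edge_label, accepted, ci, pos, old[pos], new_nt, synonymous))
            accepted += 1
    if accepted < n_accept:
        import warnings

        warnings.warn(f"edge {edge_label}: only {accepted}/{n_accept} mutations accepted")


def build_true_tree(config: SimulationConfig) -> dendropy.Tree:
    """Parse the scenario tree and graft the transferred copy at the event."""
    tree = dendropy.Tree.get(
        data=config.newick, schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    for i, node in enumerate(tree.preorder_node_iter()):
        if node.taxon is None and node.label is None and node.parent_node is not None:
            node.label = f"node{i}"
    ev = config.egt_event
    if ev is None:
        return tree
    target = _find_node(tree, ev.branch)
    if target is tree.seed_node:
        raise ValueError("transfer event cannot sit on the root")
    b = target.edge.length or 0.0
    t = ev.time_fraction
    if not 0.0 <= t <= 1.0:
        raise ValueError("time_fraction outside [0, 1]")
    parent = target.parent_node
    mid = dendropy.Node(label=f"egt_{ev.new_name}")
    parent.remove_child(target)
    parent.add_child(mid)
    mid.edge.length = t * b
    mid.add_child(target)
    target.edge.length = (1.0 - t) * b
    tip = dendropy.Node()
    tip.taxon = dendropy.Taxon(label=ev.new_name)
    tree.taxon_namespace.add_taxon(tip.taxon)
    mid.add_child(tip)
    tip.edge.length = (1.0 - t) * b
    return tree


def _find_node(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for node in tree.preorder_node_iter():
        if (node.taxon is not None and node.taxon.label == label) or node.label == label:
            return node
    raise ValueError(f"event branch {label!r} not found in tree")


def _node_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else (node.label or "root")


def _compartment_of(node: dendropy.Node, config: SimulationConfig, inherited: str) -> str:
    label = _node_label(node)
    if config.egt_event is not None and label == config.egt_event.new_name:
        return config.egt_event.new_compartment
    return config.compartments.get(label, inherited)


# ---------------------------------------------------------------------------
# main entry points


def simulate_egt(config: SimulationConfig) -> tuple[list[CodingGene], TruthSet]:
    """Evolve the gene family and return emitted genes plus ground truth."""
    rng = np.random.default_rng(config.seed)
    code = genetic_code(config.genetic_code_id)
    tree = build_true_tree(config)
    root_bias = config.at_bias[config.root_compartment]
    root_cds = _random_root_cds(config.root_cds_length, code, root_bias, rng)
    log: list = []
    genes: list[CodingGene] = []
    compartments: dict[str, str] = {}

    def walk(node: dendropy.Node, cds: list[str], compartment: str) -> None:
        for child in node.child_nodes():
            child_comp = _compartment_of(child, config, compartment)
            child_cds = list(cds)
            b = child.edge.length or 0.0
            n_accept = int(rng.poisson(b * config.root_cds_length))
            _evolve_branch(
                child_cds,
                n_accept,
                code,
                config.at_bias[child_comp],
                config.p_nonsyn_accept,
                rng,
                _node_label(child),
                log,
            )
            if child.is_leaf():
                name = child.taxon.label
                compartments[name] = child_comp
                genes.append(_emit(name, "".join(child_cds), child_comp, config))
            else:
                walk(child, child_cds, child_comp)

    root_codons = [root_cds[i : i + 3] for i in range(0, len(root_cds), 3)]
    walk(tree.seed_node, root_codons, config.root_compartment)

    presequence = None
    ev = config.egt_event
    if ev is not None and config.presequence_insert is not None:
        genes, presequence = _plant_presequence(genes, config, rng)

    truth = TruthSet(
        tree=tree,
        root_cds=root_cds,
        compartments=compartments,
        mutation_log=pd.DataFrame(log, columns=_LOG_COLUMNS),
        transferred_id=ev.new_name if ev else None,
        donor_id=ev.branch if ev else None,
        presequence=presequence,
        config=config,
    )
    return genes, truth


def _emit(name: str, cds: str, compartment: str, config: SimulationConfig) -> CodingGene:
    return CodingGene(
        id=name,
        taxon=name,
        compartment=compartment,
        group=compartment,
        cds=cds,
        genetic_code_id=config.genetic_code_id,
    )


def _reverse_translate(aa: str, code: GeneticCode, at3: float, rng: np.random.Generator) -> str:
    by_aa = _synonym_sets(code)
    out = []
    for a in aa.upper():
        codons = by_aa[a]
        weights = np.array([at3 if c[2] in AT else 1.0 - at3 for c in codons])
        weights = weights / weights.sum()
        out.append(codons[rng.choice(len(codons), p=weights)])
    return "".join(out)


def _plant_presequence(
    genes: list[CodingGene], config: SimulationConfig, rng: np.random.Generator
):
    ins = config.presequence_insert
    ev = config.egt_event
    template = ins.signal_peptide + ins.transit_peptide
    at3 = config.at_bias[ev.new_compartment]
    code = genetic_code(config.genetic_code_id)
    out = []
    presequence = None
    for g in genes:
        if g.id != ev.new_name:
            out.append(g)
            continue
        insert_nt = _reverse_translate(template, code, at3, rng)
        out.append(replace(g, cds=insert_nt + g.cds))
        sp_len, tp_len = len(ins.signal_peptide), len(ins.transit_peptide)
        presequence = {
            "gene": g.id,
            "sp_span": (1, sp_len),
            "cleavage_site": sp_len,
            "tp_span": (sp_len + 1, sp_len + tp_len),
            "length": sp_len + tp_len,
        }
    return out, presequence


def replay_truth(truth: TruthSet, genes: list[CodingGene]) -> None:
    """Replay the mutation log root-to-tip and check it reproduces every
    emitted CDS exactly (presequence inserts excluded).  Raises on any
    mismatch or truncated log."""
    by_id = {g.id: g for g in genes}
    log_by_edge: dict[str, list] = {}
    for row in truth.mutation_log.itertuples(index=False):
        log_by_edge.setdefault(row.edge, []).append(row)

    def walk(node: dendropy.Node, cds: list[str]) -> None:
        for child in node.child_nodes():
            label = _node_label(child)
            child_cds = list(cds)
            for row in log_by_edge.get(label, []):
                codon = child_cds[row.codon_index]
                if codon[row.position] != row.from_nt:
                    raise ValueError(
                        f"log integrity failure on edge {label}: codon {row.codon_index} "
                        f"has {codon[row.position]} where log expects {row.from_nt}"
                    )
                child_cds[row.codon_index] = (
                    codon[: row.position] + row.to_nt + codon[row.position + 1 :]
                )
            if child.is_leaf():
                name = child.taxon.label
                rebuilt = "".join(child_cds)
                emitted = by_id[name].cds
                if truth.presequence is not None and name == truth.presequence["gene"]:
                    emitted = emitted[3 * truth.presequence["length"] :]
                if rebuilt != emitted:
                    raise ValueError(f"replay mismatch for gene {name}")
            else:
                walk(child, child_cds)

    root = [truth.root_cds[i : i + 3] for i in range(0, len(truth.root_cds), 3)]
    walk(truth.tree.seed_node, root)


# ---------------------------------------------------------------------------
# scenario + recovery experiment


def default_scenario(seed: int = 0, **overrides) -> SimulationConfig:
    """The package's reference transfer scenario.

    A plastid clade of four AT-regime lineages and a nuclear clade of four
    GC-regime lineages (long-resident homologues); the transfer event
    duplicates the gene part-way along the terminal branch of plastid tip
    ``P1``, the copy switching to the nuclear regime — emulating a diatom
    gene recently moved from plastid to nucleus, with the transferred copy
    on a long branch.
    """
    newick = (
        "((P1:0.5,P2:0.35)pl1:0.2,(P3:0.35,P4:0.35)pl2:0.2,"
        "((N1:0.45,N2:0.45)nu1:0.2,(N3:0.45,N4:0.45)nu2:0.2)nu:0.45)root;"
    )
    cfg = dict(
        newick=newick,
        root_cds_length=120,
        compartments={"nu": "nuclear"},
        root_compartment="plastid",
        at_bias={"plastid": 0.70, "nuclear": 0.45, "cyanobacterial": 0.55},
        p_nonsyn_accept=0.15,
        egt_event=EgtEvent(
            branch="P1", time_fraction=0.3, new_compartment="nuclear", new_name="T_nu"
        ),
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def saturated_scenario(seed: int = 0, **overrides) -> SimulationConfig:
    """A transfer scenario in the saturated, artifact-prone regime.

    Same compartment biases as :func:`default_scenario`, but deep
    divergences, weaker purifying selection and a transfer early on the
    donor's terminal branch, so the transferred copy sits on the longest
    branch in the tree — the regime where conventional distance methods
    misplace it with the like-composition clade in a large fraction of
    replicates.  This is the condition for the method-comparison
    experiments.
    """
    cfg = dict(
        newick=(
            "((P1:2.5,P2:0.5)pl1:0.3,(P3:0.5,P4:0.5)pl2:0.3,"
            "((N1:1.4,N2:1.4)nu1:0.4,(N3:1.4,N4:1.4)nu2:0.4)nu:0.9)root;"
        ),
        root_cds_length=120,
        compartments={"nu": "nuclear"},
        root_compartment="plastid",
        at_bias={"plastid": 0.70, "nuclear": 0.45, "cyanobacterial": 0.55},
        p_nonsyn_accept=0.45,
        egt_event=EgtEvent(
            branch="P1", time_fraction=0.06, new_compartment="nuclear", new_name="T_nu"
        ),
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def genes_to_alignment(genes: list[CodingGene]) -> ProteinAlignment:
    """Translated, gap-free protein alignment (the simulator emits no indels)."""
    rows = [g.protein for g in genes]
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ValueError("genes differ in protein length; alignment required")
    return ProteinAlignment(ids=[g.id for g in genes], rows=rows)


def _sister_placement(
    tree: dendropy.Tree, transferred: str, donor: str, foreign: set[str]
) -> tuple[bool, bool]:
    """(sister to true paralog?, grouped inside the foreign clade?)."""
    from .phylo_saturation import leaf_labels, tree_splits

    splits = tree_splits(tree)
    all_leaves = leaf_labels(tree)
    pair = frozenset({transferred, donor})
    with_paralog = pair in splits or frozenset(all_leaves - pair) in splits
    with_foreign = False
    for s in splits:
        side = s if transferred in s else all_leaves - s
        if transferred in side and len(side) < len(all_leaves) - 1:
            rest = side - {transferred}
            if rest and rest <= foreign:
                with_foreign = True
                break
    return with_paralog, with_foreign


def recovery_experiment(
    config: SimulationConfig,
    methods: list[str] | None = None,
    n_seeds: int = 50,
    cutoff: float | None = None,
) -> pd.DataFrame:
    """Compare tree methods on replicate simulations against ground truth.

    Per method: mean Robinson-Foulds distance to the true tree, fraction
    of seeds placing the transferred copy sister to its true paralog, and
    fraction attaching it inside the like-composition foreign clade.
    Seeds are ``config.seed + k`` for k in 0..n_seeds-1.
    """
    from . import phylo_saturation as ps

    methods = methods or ["NJ-plain", "NJ-filtered", "MP"]
    model = ps.lg_model(cutoff=cutoff) if cutoff is not None else ps.lg_model()
    builders = {
        "NJ-plain": ps.nj_plain_builder,
        "NJ-filtered": ps.nj_filtered_builder(model),
        "MP": ps.mp_builder(),
    }
    unknown = set(methods) - set(builders)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    tallies = {m: {"rf": [], "paralog": 0, "foreign": 0} for m in methods}
    for k in range(n_seeds):
        cfg = replace(config, seed=config.seed + k)
        genes, truth = simulate_egt(cfg)
        aln = genes_to_alignment(genes)
        foreign = {
            g.id
            for g in genes
            if g.compartment == cfg.egt_event.new_compartment and g.id != truth.transferred_id
        }
        for m in methods:
            tree = builders[m](aln)
            tallies[m]["rf"].append(ps.rf_distance(tree, truth.tree))
            with_paralog, with_foreign = _sister_placement(
                tree, truth.transferred_id, truth.donor_id, foreign
            )
            tallies[m]["paralog"] += with_paralog
            tallies[m]["foreign"] += with_foreign
    rows = []
    for m in methods:
        t = tallies[m]
        rows.append(
            {
                "method": m,
                "n_seeds": n_seeds,
                "mean_rf": float(np.mean(t["rf"])),
                "sister_to_paralog_fraction": t["paralog"] / n_seeds,
                "with_foreign_clade_fraction": t["foreign"] / n_seeds,
            }
        )
    return pd.DataFrame(rows)
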