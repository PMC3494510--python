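"""Final evidence integration: monophyly, families, architecture, categories.

A screened candidate becomes *algal_phylogenetic* when the bootstrap tree of
its homolog set contains a clade uniting all recipient-group sequences with
at least one donor-group sequence, no sequence from any other group, and
split support at or above the threshold (default 70).  A candidate whose
tree is uninformative (or unbuildable) but whose homologs occur only in
donor groups is *algal_distribution_only*.  Remaining screened candidates
are *candidate_unresolved*; everything else is *rejected*.

Algae-related genes are grouped into families by single-linkage clustering
on pairwise percent identity; shared domain-architecture between the query
and donor sequences (exclusive of all other non-recipient groups) is
recorded as corroborating evidence only and never changes a category.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .alien_screen import (
    AlienScore,
    ScreenConfig,
    alien_scores_from_hits,
    hit_table,
    global_identity,
)
from .errors import DataError
from .io_formats import (
    DomainAnnotation,
    NONDONOR_ROLES,
    SequenceRecord,
    TaxonomyMap,
    read_domain_table,
    read_fasta,
    read_taxonomy_config,
    write_newick,
)
from .msa import progressive_align, trim_alignment
from .tree_inference import bootstrap_trees, map_support, nj_tree, protein_distance
from .trees import SupportTree

logger = logging.getLogger(__name__)

CATEGORIES = (
    "algal_phylogenetic",
    "algal_distribution_only",
    "candidate_unresolved",
    "rejected",
)


@dataclass(frozen=True)
class MonophylyCall:
    """Result of the donor+recipient clade test on one unrooted tree."""

    query_id: str
    clade_members: frozenset
    clade_support: int
    informative: bool
    verdict: str  # pass | fail | uninformative


@dataclass
class GeneFamily:
    family_id: str
    members: List[str]
    identity_min: Optional[float]
    identity_max: Optional[float]
    shared_topology_note: str = ""


@dataclass
class GeneCall:
    query_id: str
    alien: AlienScore
    monophyly: Optional[MonophylyCall]
    architecture_shared: Optional[bool]
    category: str


def monophyly_test(
    tree: SupportTree,
    recipient_ids: Sequence[str],
    donor_ids: Sequence[str],
    support_min: int = 70,
    query_id: str = "",
) -> MonophylyCall:
    """Search all bipartitions for a supported donor+recipient clade.

    A side S qualifies when it contains every recipient leaf, at least one
    donor leaf, and nothing else.  Trivial splits (one leaf against the
    rest) count as support 100 where they qualify, with one exception: a
    side whose complement is a single outside-group leaf is present in
    every possible tree on the same leaves (it is tautological) and is
    therefore never evidence of monophyly — a tree in which recipients
    interleave with outside groups must not pass just because the lone
    outside leaf has its own pendant edge.  With no leaf outside
    donor+recipient the test carries no information and the verdict is
    'uninformative'.  Among qualifying supported sides the smallest is
    reported; if none is supported, the smallest qualifying side is
    reported with verdict 'fail'.
    """
    leaves = tree.leaf_set()
    recipients = frozenset(recipient_ids)
    if not recipients:
        raise DataError("recipient_ids must be non-empty")
    missing = recipients - leaves
    if missing:
        raise DataError(f"recipient id(s) absent from tree: {sorted(missing)}")
    donors = frozenset(donor_ids) & leaves
    if recipients & donors:
        raise DataError("donor and recipient id sets overlap")
    informative = bool(leaves - recipients - donors)
    if not informative:
        return MonophylyCall(query_id, frozenset(), 0, False, "uninformative")

    allowed = recipients | donors

    def qualifies(side: frozenset) -> bool:
        return recipients <= side and side <= allowed and bool(side & donors)

    qualifying: List[Tuple[frozenset, int]] = []
    for split in tree.splits(include_trivial=True):
        for side in (split.side, frozenset(leaves - split.side)):
            if not qualifies(side):
                continue
            comp = leaves - side
            if len(comp) == 1 and not (comp & allowed):
                continue  # tautological: complement is one outside leaf
            if split.trivial:
                support = 100
            else:
                support = split.support if split.support is not None else 0
            qualifying.append((side, support))
    supported = [(s, sup) for s, sup in qualifying if sup >= support_min]
    if supported:
        side, sup = min(supported, key=lambda x: (len(x[0]), sorted(x[0])))
        return MonophylyCall(query_id, side, sup, True, "pass")
    if qualifying:
        side, sup = min(qualifying, key=lambda x: (len(x[0]), sorted(x[0])))
        return MonophylyCall(query_id, side, sup, True, "fail")
    return MonophylyCall(query_id, frozenset(), 0, True, "fail")


def cluster_families(
    query_ids: Sequence[str],
    identity_fn: Callable[[str, str], float],
    link: float = 0.30,
) -> List[GeneFamily]:
    """Single-linkage families at pairwise identity >= ``link`` (fraction).

    ``identity_fn`` returns percent identity between two query ids.
    Families are ordered (and named) by their smallest member id.
    """
    ids = list(query_ids)
    n = len(ids)
    if n == 0:
        return []
    ident = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = identity_fn(ids[i], ids[j])
    adj = csr_matrix(ident >= link * 100.0)
    _, comp = connected_components(adj, directed=False)
    groups: Dict[int, List[str]] = {}
    for idx, c in enumerate(comp):
        groups.setdefault(c, []).append(ids[idx])
    families = sorted((sorted(m) for m in groups.values()), key=lambda m: m[0])
    out = []
    for k, members in enumerate(families, start=1):
        if len(members) > 1:
            pos = [ids.index(m) for m in members]
            vals = [ident[i, j] for i in pos for j in pos if i < j]
            imin, imax = float(min(vals)), float(max(vals))
        else:
            imin = imax = None
        out.append(GeneFamily(f"F{k:02d}", members, imin, imax))
    return out


def architecture_of(annotations: Sequence[DomainAnnotation], seq_id: str) -> Tuple[str, ...]:
    doms = sorted(
        (a for a in annotations if a.seq_id == seq_id), key=lambda a: (a.start, a.end)
    )
    return tuple(a.domain for a in doms)


def shared_architecture_test(
    annotations: Optional[Sequence[DomainAnnotation]],
    taxonomy: TaxonomyMap,
    query_id: str,
) -> Optional[bool]:
    """Is the query's ordered domain architecture donor-exclusive?

    True when at least one donor-group sequence shares the exact ordered
    architecture and no close_relative / other_eukaryote / prokaryote
    sequence does.  Recipient-group matches neither help nor hurt.  Returns
    None when no annotations are available for the query.
    """
    if not annotations:
        return None
    arch = architecture_of(annotations, query_id)
    if not arch:
        return None
    seq_ids = {a.seq_id for a in annotations} - {query_id}
    in_donor = False
    for sid in seq_ids:
        if architecture_of(annotations, sid) != arch:
            continue
        role = taxonomy.role_of_id(sid)
        if role == "donor":
            in_donor = True
        elif role in NONDONOR_ROLES:
            return False
    return in_donor


def classify_gene(
    alien: AlienScore,
    monophyly: Optional[MonophylyCall],
    architecture: Optional[bool] = None,
) -> GeneCall:
    """Apply the decision table; architecture is corroborative only."""
    if monophyly is not None and monophyly.verdict == "pass":
        category = "algal_phylogenetic"
    elif alien.donor_only and (monophyly is None or monophyly.verdict == "uninformative"):
        category = "algal_distribution_only"
    elif alien.candidate:
        category = "candidate_unresolved"
    else:
        category = "rejected"
    return GeneCall(alien.query_id, alien, monophyly, architecture, category)


# ------------------------------------------------------------ orchestration


@dataclass
class PipelineConfig:
    """All thresholds of the end-to-end screen, with their defaults.

    tau_ratio: bit-score ratio above which a query is a candidate (strict).
    support_min: minimum bootstrap support for the donor+recipient clade.
    n_boot: number of bootstrap pseudoreplicates.
    identity_link: single-linkage identity threshold (fraction) for families.
    homolog_min_bits: bit-score floor defining an identifiable homolog.
    gap_max_frac / min_majority_frac: alignment column-trimming rules.
    lambda_ / k_: Karlin-Altschul constants of the bit-score conversion.
    """

    tau_ratio: float = 1.5
    support_min: int = 70
    n_boot: int = 100
    identity_link: float = 0.30
    homolog_min_bits: float = 50.0
    gap_max_frac: float = 0.5
    min_majority_frac: float = 0.0
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lambda_: float = 0.267
    k_: float = 0.041
    seed: int = 0

    def __post_init__(self):
        if self.tau_ratio <= 0:
            raise DataError("tau_ratio must be positive")
        if not 0 <= self.support_min <= 100:
            raise DataError("support_min must be in [0, 100]")
        if self.n_boot < 1:
            raise DataError("n_boot must be >= 1")
        if not 0 < self.identity_link < 1:
            raise DataError("identity_link must be in (0, 1)")

    def screen_config(self) -> ScreenConfig:
        return ScreenConfig(
            tau_ratio=self.tau_ratio,
            homolog_min_bits=self.homolog_min_bits,
            matrix=self.matrix,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
            lambda_=self.lambda_,
            k_=self.k_,
        )

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class PipelineResult:
    calls: List[GeneCall]
    families: List[GeneFamily]
    trees: Dict[str, SupportTree]
    summary: dict


def _candidate_tree(
    query: SequenceRecord,
    homologs: List[SequenceRecord],
    config: PipelineConfig,
    seed: int,
) -> Optional[SupportTree]:
    """Aligned, trimmed, bootstrapped NJ tree of a candidate's homolog set."""
    records = sorted([query] + homologs, key=lambda r: r.id)
    if len(records) < 3:
        return None
    aln = progressive_align(records, gap_open=config.gap_open, gap_extend=config.gap_extend)
    aln = trim_alignment(aln, config.gap_max_frac, config.min_majority_frac)
    dm = protein_distance(aln)
    best = nj_tree(dm)
    reps = bootstrap_trees(
        aln, n_reps=config.n_boot, seed=seed, taxon_namespace=best.tree.taxon_namespace
    )
    return map_support(best, reps)


def run_pipeline(
    query_fasta,
    subject_fasta,
    taxonomy_path,
    outdir,
    config: PipelineConfig = PipelineConfig(),
    domains_path=None,
) -> PipelineResult:
    """Screen a proteome end to end and write all reports.

    Writes ``gene_calls.tsv`` (screening scores, monophyly and category per
    query), ``families.tsv``, one Newick per candidate under ``trees/`` and
    a JSON ``summary.json``.
    Deterministic under a fixed config (including its seed).
    """
    outdir = Path(outdir)
    (outdir / "trees").mkdir(parents=True, exist_ok=True)
    queries = read_fasta(query_fasta, "protein")
    subjects = read_fasta(subject_fasta, "protein")
    taxonomy = read_taxonomy_config(taxonomy_path)
    annotations = read_domain_table(domains_path) if domains_path else None
    subj_by_id = {r.id: r for r in subjects}

    logger.info("screening %d queries against %d subjects", len(queries), len(subjects))
    scfg = config.screen_config()
    hits = hit_table(queries, subjects, taxonomy, scfg)
    scores = {s.query_id: s for s in alien_scores_from_hits(hits, taxonomy, scfg)}

    seed_seq = np.random.SeedSequence(config.seed)
    calls: List[GeneCall] = []
    trees: Dict[str, SupportTree] = {}
    candidates = [q for q in queries if scores[q.id].candidate]
    child_seeds = seed_seq.spawn(len(candidates))
    seed_of = {q.id: int(s.generate_state(1)[0] % (2**31)) for q, s in zip(candidates, child_seeds)}

    for query in queries:
        alien = scores[query.id]
        mono = None
        arch = None
        if alien.candidate:
            homolog_ids = [h.subject_id for h in hits[query.id]]
            homologs = [subj_by_id[h] for h in homolog_ids]
            tree = _candidate_tree(query, homologs, config, seed_of[query.id])
            if tree is not None:
                recipient_ids = [
                    lab
                    for lab in tree.leaf_labels()
                    if taxonomy.role_of_id(lab) == "recipient" or lab == query.id
                ]
                donor_ids = [
                    lab
                    for lab in tree.leaf_labels()
                    if lab != query.id and taxonomy.role_of_id(lab) == "donor"
                ]
                mono = monophyly_test(
                    tree, recipient_ids, donor_ids, config.support_min, query.id
                )
                trees[query.id] = tree
            arch = shared_architecture_test(annotations, taxonomy, query.id)
        calls.append(classify_gene(alien, mono, arch))

    algae_related = [
        c.query_id
        for c in calls
        if c.category in ("algal_phylogenetic", "algal_distribution_only")
    ]
    seq_of = {q.id: q.seq for q in queries}
    ident_cache: Dict[Tuple[str, str], float] = {}

    def identity_fn(a: str, b: str) -> float:
        key = (min(a, b), max(a, b))
        if key not in ident_cache:
            ident_cache[key] = global_identity(
                seq_of[a], seq_of[b], matrix=config.matrix,
                gap_open=config.gap_open, gap_extend=config.gap_extend,
            )
        return ident_cache[key]

    families = cluster_families(algae_related, identity_fn, config.identity_link)
    _annotate_topology_notes(families, trees)

    summary = {
        "n_queries": len(queries),
        "n_subjects": len(subjects),
        "n_candidates": len(candidates),
        "categories": {
            cat: sum(c.category == cat for c in calls) for cat in CATEGORIES
        },
        "n_families": len(families),
        "config": config.to_dict(),
    }
    _write_reports(outdir, calls, families, trees, summary)
    return PipelineResult(calls, families, trees, summary)


def _annotate_topology_notes(families: List[GeneFamily], trees: Dict[str, SupportTree]):
    """Informational note on topology similarity between member trees.

    Normalised Robinson-Foulds distance over the shared leaves of each
    member pair's trees; purely descriptive, never a clustering gate.
    """
    import dendropy
    from dendropy.calculate import treecompare

    for fam in families:
        with_trees = [m for m in fam.members if m in trees]
        if len(with_trees) < 2:
            fam.shared_topology_note = ""
            continue
        rfs = []
        for i in range(len(with_trees)):
            for j in range(i + 1, len(with_trees)):
                a, b = trees[with_trees[i]], trees[with_trees[j]]
                shared = (a.leaf_set() & b.leaf_set()) - set(fam.members)
                if len(shared) < 4:
                    continue
                try:
                    tns = dendropy.TaxonNamespace(sorted(shared))
                    ta = dendropy.Tree.get(
                        data=a.to_newick(), schema="newick",
                        taxon_namespace=tns, preserve_underscores=True,
                        suppress_internal_node_taxa=True,
                    )
                    tb = dendropy.Tree.get(
                        data=b.to_newick(), schema="newick",
                        taxon_namespace=tns, preserve_underscores=True,
                        suppress_internal_node_taxa=True,
                    )
                    keep = [tns.get_taxon(x) for x in sorted(shared)]
                    ta.retain_taxa(keep)
                    tb.retain_taxa(keep)
                    ta.encode_bipartitions()
                    tb.encode_bipartitions()
                    rf = treecompare.symmetric_difference(ta, tb)
                    denom = 2 * max(len(shared) - 3, 1)
                    rfs.append(rf / denom)
                except Exception:  # pragma: no cover - best-effort note
                    continue
        fam.shared_topology_note = (
            f"mean normalised RF over shared leaves: {np.mean(rfs):.2f}" if rfs else ""
        )


def _write_reports(outdir: Path, calls, families, trees, summary):
    def fmt(x, nd=3):
        return "" if x is None else f"{x:.{nd}f}"

    rows = []
    for c in calls:
        rows.append(
            {
                "query_id": c.query_id,
                "best_donor_bits": fmt(c.alien.best_donor_bits, 2),
                "best_nondonor_bits": fmt(c.alien.best_nondonor_bits, 2),
                "ratio": fmt(c.alien.ratio, 4),
                "donor_only": c.alien.donor_only,
                "candidate": c.alien.candidate,
                "monophyly_verdict": c.monophyly.verdict if c.monophyly else "",
                "clade_support": c.monophyly.clade_support if c.monophyly else "",
                "clade_members": ";".join(sorted(c.monophyly.clade_members)) if c.monophyly else "",
                "architecture_shared": "" if c.architecture_shared is None else c.architecture_shared,
                "category": c.category,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "gene_calls.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "family_id": f.family_id,
                "members": ";".join(f.members),
                "identity_min": fmt(f.identity_min, 1),
                "identity_max": fmt(f.identity_max, 1),
                "topology_note": f.shared_topology_note,
            }
            for f in families
        ]
    ).to_csv(outdir / "families.tsv", sep="\t", index=False)
    for qid, tree in trees.items():
        write_newick(tree, outdir / "trees" / f"{qid}.nwk")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
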