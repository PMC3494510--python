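"""Simulated multi-group proteomes with implanted horizontal transfers.

The generator emulates the inputs of an algal-gene screen of an animal
proteome: a species tree with three labelled clades (donor algae, recipient
animals, other eukaryotes), one protein family per gene, and a known subset
of recipient-clade families whose sequences descend from a donor lineage
rather than from the vertical ancestor.

Sequences evolve under a 20-state equal-rates (Poisson) substitution model,
chosen because it admits a closed-form identity decay,

    P(site identical) = 1/20 + (19/20) * exp(-(20/19) * d),

at path distance d (in expected substitutions/site), which serves as an
analytic oracle for the whole simulator.  No indels are simulated.

The species tree has four labelled clades arranged as
((recipient, close_relative), (donor, other_eukaryote)): animals with their
fungal relatives on one side of the central edge, algae with other
plastid-bearing eukaryotes on the other.  Non-donor lineages therefore sit
on both sides of the tree, which is what makes the monophyly test
informative: for a vertically inherited family no tree split unites all
recipients with a donor to the exclusion of everything else, while for a
transferred family the recipient clade nests inside the donor clade and
such splits exist.

Clade geometry (fractions of ``vertical_depth`` v): within-clade subtrees
are ultrametric of height h = v/8 (within-clade leaf-to-leaf distances up
to v/4); stems are v/4 (recipient, close_relative), v/8 (donor,
other_eukaryote), and the central edge is 3v/8.  Leaf-to-leaf separations
are then exactly v between recipient and donor (and across every other
deep pair), 3v/4 between recipient and close_relative, and v/2 between
donor and other_eukaryote (plastid-bearing protists share more gene content
with algae).  At the default v = 1.2 most within-family identities fall in
the 30-80% band typical of curated cross-kingdom gene families.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from .errors import DataError
from .io_formats import SequenceRecord, TaxonomyMap, write_fasta, write_taxonomy_config
from .trees import SupportTree

logger = logging.getLogger(__name__)

AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
N_STATES = 20


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    n_donor_taxa: int = 6
    n_recipient_taxa: int = 6
    n_other_taxa: int = 4
    n_families: int = 50
    transfer_fraction: float = 0.2
    seq_len: int = 300
    vertical_depth: float = 1.2
    transfer_depth: float = 0.3
    rate_jitter: Tuple[float, float] = (0.9, 1.1)
    seed: int = 0
    n_close_taxa: int = 4

    def __post_init__(self):
        for name in ("n_donor_taxa", "n_recipient_taxa", "n_other_taxa", "n_families"):
            if getattr(self, name) < 1:
                raise DataError(f"{name} must be >= 1")
        if self.n_close_taxa < 0:
            raise DataError("n_close_taxa must be >= 0")
        if not 0 <= self.transfer_fraction <= 1:
            raise DataError("transfer_fraction must be in [0, 1]")
        if self.seq_len < 1:
            raise DataError("seq_len must be >= 1")
        if self.vertical_depth <= 0 or self.transfer_depth < 0:
            raise DataError("depths must be positive")
        lo, hi = self.rate_jitter
        if not 0 < lo <= hi:
            raise DataError("rate_jitter must be an increasing positive pair")
        if self.transfer_depth >= self.vertical_depth:
            warnings.warn(
                "transfer_depth >= vertical_depth: transfers may be undetectable",
                stacklevel=2,
            )

    @property
    def donor_taxa(self) -> List[str]:
        return [f"alga{i:02d}" for i in range(1, self.n_donor_taxa + 1)]

    @property
    def recipient_taxa(self) -> List[str]:
        return [f"anim{i:02d}" for i in range(1, self.n_recipient_taxa + 1)]

    @property
    def other_taxa(self) -> List[str]:
        return [f"euk{i:02d}" for i in range(1, self.n_other_taxa + 1)]

    @property
    def close_taxa(self) -> List[str]:
        return [f"fung{i:02d}" for i in range(1, self.n_close_taxa + 1)]

    @property
    def all_taxa(self) -> List[str]:
        return self.donor_taxa + self.recipient_taxa + self.close_taxa + self.other_taxa


@dataclass
class FamilyTruth:
    family_id: str
    transferred: bool
    donor_source_taxon: Optional[str]
    identity_min: float = float("nan")
    identity_median: float = float("nan")
    identity_max: float = float("nan")


TruthTable = List[FamilyTruth]


def truth_to_frame(truth: TruthTable) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family_id": t.family_id,
                "transferred": t.transferred,
                "donor_source_taxon": t.donor_source_taxon or "",
                "identity_min": round(t.identity_min, 4),
                "identity_median": round(t.identity_median, 4),
                "identity_max": round(t.identity_max, 4),
            }
            for t in truth
        ]
    )


def read_truth_table(path) -> TruthTable:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        FamilyTruth(
            str(r["family_id"]),
            bool(r["transferred"]),
            str(r["donor_source_taxon"]) or None,
            float(r["identity_min"]),
            float(r["identity_median"]),
            float(r["identity_max"]),
        )
        for _, r in df.iterrows()
    ]


# ------------------------------------------------------------ species tree


def _balanced_clade(taxa: Sequence[str], height: float, tns) -> dendropy.Node:
    """Balanced subtree whose leaves all lie exactly ``height`` below it.

    The returned node's own edge length is left to the caller.
    """
    if len(taxa) == 1:
        return dendropy.Node(taxon=tns.get_taxon(taxa[0]) or tns.new_taxon(taxa[0]))
    parent = dendropy.Node()
    half = (len(taxa) + 1) // 2
    for part in (taxa[:half], taxa[half:]):
        child = _balanced_clade(part, height / 2, tns)
        child.edge.length = height if len(part) == 1 else height / 2
        parent.add_child(child)
    return parent


def simulate_species_tree(config: SimulationConfig) -> SupportTree:
    """Fixed-shape species tree: ((recipient, close), (donor, other)).

    Deterministic (the shape carries no randomness); branch lengths are in
    expected substitutions per site.  See the module docstring for the
    geometry; the close_relative clade is omitted when n_close_taxa is 0.
    """
    v = config.vertical_depth
    h = v / 8.0
    tns = dendropy.TaxonNamespace(config.all_taxa)
    tree = dendropy.Tree(taxon_namespace=tns)
    seed = tree.seed_node

    def clade(taxa, stem):
        node = _balanced_clade(taxa, h, tns)
        # a singleton clade is its own leaf: fold the clade height into the stem
        node.edge.length = stem + h if len(taxa) == 1 else stem
        return node

    seed.add_child(clade(config.recipient_taxa, v / 4))
    if config.n_close_taxa:
        seed.add_child(clade(config.close_taxa, v / 4))
    inner = dendropy.Node()
    seed.add_child(inner)
    inner.edge.length = 3 * v / 8
    inner.add_child(clade(config.donor_taxa, v / 8))
    inner.add_child(clade(config.other_taxa, v / 8))
    tree.is_rooted = False
    return SupportTree(tree)


# ---------------------------------------------------------- sequence model


def _evolve_seq(parent: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """One branch of the 20-state equal-rates model, length t subs/site."""
    if t < 0:
        raise DataError("negative branch length")
    p_diff = (N_STATES - 1) / N_STATES * (1.0 - np.exp(-N_STATES / (N_STATES - 1) * t))
    child = parent.copy()
    mask = rng.random(parent.size) < p_diff
    k = int(mask.sum())
    if k:
        # uniform among the 19 other states
        child[mask] = (child[mask] + rng.integers(1, N_STATES, size=k)) % N_STATES
    return child


def _evolve_down(node, seq: np.ndarray, rate: float, rng, out: Dict[str, np.ndarray]):
    for child in node.child_nodes():
        t = (child.edge.length or 0.0) * rate
        cseq = _evolve_seq(seq, t, rng)
        if child.is_leaf():
            out[child.taxon.label] = cseq
        else:
            _evolve_down(child, cseq, rate, rng, out)


def evolve_family(
    tree: SupportTree, seq_len: int, seed: int, rate: float = 1.0
) -> Dict[str, np.ndarray]:
    """Evolve one family down the tree; returns leaf label -> state vector.

    The root sequence is uniform-random over the 20 states; sites are
    independent; the per-family rate multiplies every branch length.
    """
    if seq_len < 1:
        raise DataError("seq_len must be >= 1")
    rng = np.random.default_rng(seed)
    root = rng.integers(0, N_STATES, size=seq_len)
    out: Dict[str, np.ndarray] = {}
    _evolve_down(tree.tree.seed_node, root, rate, rng, out)
    return out


def states_to_record(label: str, states: np.ndarray) -> SequenceRecord:
    return SequenceRecord(label, AA[states].tobytes().decode("ascii"), "protein")


def pairwise_identity(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(a == b))


# ------------------------------------------------------------ HGT implants


def plan_transfers(config: SimulationConfig, rng: np.random.Generator) -> Dict[str, str]:
    """Choose which families are transferred and from which donor taxon.

    The number of transfers is exactly round(transfer_fraction * n_families).
    """
    k = int(round(config.transfer_fraction * config.n_families))
    fams = [f"fam{i:03d}" for i in range(1, config.n_families + 1)]
    chosen = sorted(rng.choice(config.n_families, size=k, replace=False).tolist())
    donors = config.donor_taxa
    return {fams[i]: donors[int(rng.integers(len(donors)))] for i in chosen}


def _find_clade_root(tree: SupportTree, taxa: Sequence[str]):
    want = set(taxa)
    for node in tree.tree.preorder_node_iter():
        leaves = {lf.taxon.label for lf in node.leaf_iter()}
        if leaves == want:
            return node
    raise DataError("clade not found in species tree")


def implant_hgt(
    tree: SupportTree,
    families: Dict[str, Dict[str, np.ndarray]],
    truth_plan: Dict[str, str],
    config: SimulationConfig,
    seed: int,
    rates: Optional[Dict[str, float]] = None,
) -> Tuple[Dict[str, Dict[str, np.ndarray]], TruthTable]:
    """Replace recipient-clade sequences of planned families with transfers.

    For a transferred family the recipient subtree is re-evolved from the
    donor source taxon's sequence: the new recipient ancestor sits
    ``transfer_depth`` substitutions/site beyond the source leaf, and the
    recipient clade's own topology and branch lengths are reused below it.
    All other sequences are untouched.
    """
    if config.transfer_depth >= config.vertical_depth:
        warnings.warn(
            "transfer_depth >= vertical_depth: transfers may be undetectable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    rec_root = _find_clade_root(tree, config.recipient_taxa)
    out: Dict[str, Dict[str, np.ndarray]] = {}
    truth: TruthTable = []
    for fam_id, seqs in families.items():
        rate = (rates or {}).get(fam_id, 1.0)
        if fam_id in truth_plan:
            source = truth_plan[fam_id]
            new_seqs = dict(seqs)
            anc = _evolve_seq(seqs[source], config.transfer_depth * rate, rng)
            sub: Dict[str, np.ndarray] = {}
            if rec_root.is_leaf():
                sub[rec_root.taxon.label] = anc
            else:
                _evolve_down(rec_root, anc, rate, rng, sub)
            new_seqs.update(sub)
            out[fam_id] = new_seqs
            truth.append(FamilyTruth(fam_id, True, source))
        else:
            out[fam_id] = seqs
            truth.append(FamilyTruth(fam_id, False, None))
    for t in truth:
        idents = _family_identity_summary(out[t.family_id])
        t.identity_min, t.identity_median, t.identity_max = idents
    return out, truth


def _family_identity_summary(seqs: Dict[str, np.ndarray]) -> Tuple[float, float, float]:
    labels = sorted(seqs)
    idents = [
        pairwise_identity(seqs[a], seqs[b])
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
    ]
    arr = np.array(idents)
    return float(arr.min()), float(np.median(arr)), float(arr.max())


# ------------------------------------------------------------ full dataset


def default_taxonomy(config: SimulationConfig) -> TaxonomyMap:
    groups = {
        "algae": {"role": "donor", "patterns": ["alga"]},
        "animals": {"role": "recipient", "patterns": ["anim"]},
        "plastid_eukaryotes": {"role": "other_eukaryote", "patterns": ["euk"]},
    }
    if config.n_close_taxa:
        groups["fungi"] = {"role": "close_relative", "patterns": ["fung"]}
    return TaxonomyMap(groups)


def generate_dataset(
    config: SimulationConfig,
) -> Tuple[Dict[str, Dict[str, np.ndarray]], TruthTable, SupportTree]:
    """Simulate every family and implant the planned transfers."""
    tree = simulate_species_tree(config)
    master = np.random.default_rng(config.seed)
    # independent child streams: family evolution, transfer plan, implants
    seeds = master.integers(0, 2**31 - 1, size=config.n_families + 2)
    lo, hi = config.rate_jitter
    rates = {
        f"fam{i:03d}": float(master.uniform(lo, hi))
        for i in range(1, config.n_families + 1)
    }
    families = {
        f"fam{i:03d}": evolve_family(
            tree, config.seq_len, int(seeds[i - 1]), rate=rates[f"fam{i:03d}"]
        )
        for i in range(1, config.n_families + 1)
    }
    plan = plan_transfers(config, np.random.default_rng(int(seeds[-2])))
    families, truth = implant_hgt(
        tree, families, plan, config, int(seeds[-1]), rates=rates
    )
    return families, truth, tree


def emit_dataset(config: SimulationConfig, outdir) -> Dict[str, Path]:
    """Write a complete synthetic screening dataset.

    Files: ``query.fasta`` (proteome of the first recipient taxon),
    ``subjects.fasta`` (all other taxa), ``taxonomy.yaml``, ``truth.tsv``,
    ``species_tree.nwk``.  Re-running with the same config is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    families, truth, tree = generate_dataset(config)
    query_taxon = config.recipient_taxa[0]
    queries, subjects = [], []
    for fam_id in sorted(families):
        for taxon in config.all_taxa:
            rec = states_to_record(f"{taxon}_{fam_id}", families[fam_id][taxon])
            (queries if taxon == query_taxon else subjects).append(rec)
    paths = {
        "query": outdir / "query.fasta",
        "subjects": outdir / "subjects.fasta",
        "taxonomy": outdir / "taxonomy.yaml",
        "truth": outdir / "truth.tsv",
        "species_tree": outdir / "species_tree.nwk",
    }
    write_fasta(queries, paths["query"])
    write_fasta(subjects, paths["subjects"])
    write_taxonomy_config(default_taxonomy(config), paths["taxonomy"])
    truth_to_frame(truth).to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["species_tree"], "w") as fh:
        fh.write(tree.to_newick() + "\n")
    return paths


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
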