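"""Similarity-based alien screening (bit-score-ratio first pass).

Each query protein is aligned (full Smith-Waterman, affine gaps, BLOSUM62)
against donor-group and non-donor-group subject databases.  A query is a
candidate horizontal acquisition when its best donor bit score exceeds its
best non-donor bit score by more than a ratio threshold (default 1.5,
strictly greater), or when it has identifiable homologs (bit score above a
floor, default 50 bits) only in donor groups.

The non-donor side is the union of close_relative, other_eukaryote and
prokaryote groups; recipient-group sequences are excluded from both sides so
that a query's own-lineage paralogs cannot mask an alien signal.

Raw alignment scores are converted to bits with fixed Karlin-Altschul
constants (lambda = 0.267, K = 0.041, the standard gapped-BLOSUM62 values),
keeping scores independent of database size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import DataError
from .io_formats import NONDONOR_ROLES, SequenceRecord, TaxonomyMap

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041
DEFAULT_TAU = 1.5
DEFAULT_HOMOLOG_MIN_BITS = 50.0


@dataclass(frozen=True)
class ScoredHit:
    """One query-subject local alignment above the homolog floor."""

    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    pct_identity: float
    group: str


@dataclass(frozen=True)
class AlienScore:
    """Per-query screening result.

    ``ratio`` is best_donor_bits / best_nondonor_bits when both sides have a
    homolog; ``donor_only`` is true when only donor groups do.  ``candidate``
    follows the screening rule: donor-only distribution, or ratio strictly
    above the threshold.
    """

    query_id: str
    best_donor_bits: Optional[float]
    best_nondonor_bits: Optional[float]
    ratio: Optional[float]
    donor_only: bool
    candidate: bool


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load(matrix)
    # affine convention: a gap of length g costs gap_open + g * gap_extend
    al.open_gap_score = -(gap_open + gap_extend)
    al.extend_gap_score = -gap_extend
    return al


def sw_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> Tuple[float, List[Tuple[int, int]]]:
    """Optimal local alignment score and aligned residue-pair indices.

    The empty alignment scores 0, so the returned raw score is never
    negative; in that case the pair list is empty.
    """
    if not a or not b:
        raise DataError("sw_align: empty sequence")
    al = _aligner(matrix, gap_open, gap_extend)
    score = al.score(a, b)
    if score <= 0:
        return 0.0, []
    best = al.align(a, b)[0]
    pairs: List[Tuple[int, int]] = []
    for (sa, ea), (sb, eb) in zip(*best.aligned):
        pairs.extend(zip(range(sa, ea), range(sb, eb)))
    return float(score), pairs


def sw_score(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Score-only fast path of :func:`sw_align`."""
    if not a or not b:
        raise DataError("sw_align: empty sequence")
    return max(float(_aligner(matrix, gap_open, gap_extend).score(a, b)), 0.0)


def percent_identity(a: str, b: str, **kwargs) -> float:
    """Percent identity over the aligned residue pairs of the optimal local alignment."""
    _, pairs = sw_align(a, b, **kwargs)
    if not pairs:
        return 0.0
    matches = sum(a[i] == b[j] for i, j in pairs)
    return 100.0 * matches / len(pairs)


def global_identity(a: str, b: str, **kwargs) -> float:
    """Identities of the optimal local alignment over the shorter sequence length.

    Unlike :func:`percent_identity` this penalises short local hits: two
    unrelated proteins sharing only a 20-residue island score a few percent
    rather than the island's internal identity, which is what family
    clustering needs.
    """
    _, pairs = sw_align(a, b, **kwargs)
    if not pairs:
        return 0.0
    matches = sum(a[i] == b[j] for i, j in pairs)
    return 100.0 * matches / min(len(a), len(b))


def bit_score(raw_score: float, lambda_: float = DEFAULT_LAMBDA, k_: float = DEFAULT_K) -> float:
    """Karlin-Altschul conversion: bits = (lambda * raw - ln K) / ln 2."""
    if raw_score < 0:
        raise DataError("raw score must be non-negative")
    if lambda_ <= 0 or not 0 < k_ < 1:
        raise DataError("invalid Karlin-Altschul constants")
    return (lambda_ * raw_score - math.log(k_)) / math.log(2.0)


@dataclass(frozen=True)
class ScreenConfig:
    """Knobs of the similarity screen."""

    tau_ratio: float = DEFAULT_TAU
    homolog_min_bits: float = DEFAULT_HOMOLOG_MIN_BITS
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lambda_: float = DEFAULT_LAMBDA
    k_: float = DEFAULT_K

    def __post_init__(self):
        if self.tau_ratio <= 0:
            raise DataError("tau_ratio must be positive")
        if self.homolog_min_bits < 0:
            raise DataError("homolog_min_bits must be non-negative")


def _alien_score_from_best(
    query_id: str,
    best_donor: Optional[float],
    best_nondonor: Optional[float],
    tau: float,
) -> AlienScore:
    donor_only = best_donor is not None and best_nondonor is None
    ratio = (
        best_donor / best_nondonor
        if best_donor is not None and best_nondonor is not None
        else None
    )
    candidate = donor_only or (ratio is not None and ratio > tau)
    return AlienScore(query_id, best_donor, best_nondonor, ratio, donor_only, candidate)


def alien_ratio(
    query: SequenceRecord,
    donor_db: Sequence[SequenceRecord],
    nondonor_db: Sequence[SequenceRecord],
    config: ScreenConfig = ScreenConfig(),
) -> AlienScore:
    """Screen one query against explicit donor / non-donor databases."""
    if not donor_db or not nondonor_db:
        raise DataError("donor and non-donor databases must be non-empty")

    def best(db):
        top = None
        for rec in db:
            if rec.id == query.id:
                logger.info("subject %r shares the query id; excluded", rec.id)
                continue
            bits = bit_score(
                sw_score(query.seq, rec.seq, config.matrix, config.gap_open, config.gap_extend),
                config.lambda_,
                config.k_,
            )
            if bits >= config.homolog_min_bits and (top is None or bits > top):
                top = bits
        return top

    return _alien_score_from_best(query.id, best(donor_db), best(nondonor_db), config.tau_ratio)


def hit_table(
    queries: Sequence[SequenceRecord],
    subject_db: Sequence[SequenceRecord],
    taxonomy: TaxonomyMap,
    config: ScreenConfig = ScreenConfig(),
) -> Dict[str, List[ScoredHit]]:
    """All query-subject hits at or above the homolog floor, grouped by query.

    Identity is not computed here (score-only alignments); hits carry
    pct_identity = -1 as a sentinel and callers needing identity use
    :func:`percent_identity`.
    """
    groups = {}
    for rec in subject_db:
        groups[rec.id] = taxonomy.resolve(rec.id)  # raises DataError if unresolved
    out: Dict[str, List[ScoredHit]] = {}
    for qi, query in enumerate(queries):
        hits: List[ScoredHit] = []
        for rec in subject_db:
            if rec.id == query.id:
                logger.info("subject %r shares the query id; excluded", rec.id)
                continue
            raw = sw_score(query.seq, rec.seq, config.matrix, config.gap_open, config.gap_extend)
            bits = bit_score(raw, config.lambda_, config.k_)
            if bits >= config.homolog_min_bits:
                hits.append(ScoredHit(query.id, rec.id, raw, bits, -1.0, groups[rec.id]))
        out[query.id] = hits
        if (qi + 1) % 25 == 0:
            logger.info("screened %d/%d queries", qi + 1, len(queries))
    return out


def alien_scores_from_hits(
    hits: Dict[str, List[ScoredHit]],
    taxonomy: TaxonomyMap,
    config: ScreenConfig = ScreenConfig(),
) -> List[AlienScore]:
    out = []
    for query_id, qhits in hits.items():
        best_donor = best_nondonor = None
        for h in qhits:
            role = taxonomy.role_of(h.group)
            if role == "donor":
                if best_donor is None or h.bit_score > best_donor:
                    best_donor = h.bit_score
            elif role in NONDONOR_ROLES:
                if best_nondonor is None or h.bit_score > best_nondonor:
                    best_nondonor = h.bit_score
            # recipient-group subjects are excluded from both sides
        out.append(_alien_score_from_best(query_id, best_donor, best_nondonor, config.tau_ratio))
    return out


def screen_proteome(
    queries: Sequence[SequenceRecord],
    subject_db: Sequence[SequenceRecord],
    taxonomy: TaxonomyMap,
    config: ScreenConfig = ScreenConfig(),
) -> List[AlienScore]:
    """Screen every query; one AlienScore per query, in input order."""
    hits = hit_table(queries, subject_db, taxonomy, config)
    return alien_scores_from_hits(hits, taxonomy, config)
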