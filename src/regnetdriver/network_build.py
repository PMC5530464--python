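"""Construction of the tissue-specific TF regulatory network.

The network is assembled in three steps: (1) define promoters (a strand-aware
window upstream of each TSS) and enhancers (distal open-chromatin regions at
least 1 kb from any gene), keeping only elements overlapping a DNase I
hypersensitive site in the target tissue; (2) accept TF binding calls at
those elements with binding probability >= 0.7; (3) propagate TF->element
binding through element->gene links into unique directed TF->target edges.
TF hubs are the top 25% of TFs by distinct-target out-degree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import GeneModel, GenomicInterval, InputError, IntervalIndex
from .stats_core import bh_adjust, spearman

log = logging.getLogger(__name__)

DEFAULT_PROMOTER_UPSTREAM = 2500
DEFAULT_MIN_GENE_DISTANCE = 1000
DEFAULT_BINDING_THRESHOLD = 0.7
DEFAULT_HUB_FRACTION = 0.25
DEFAULT_ENHANCER_WINDOW = 1_000_000


@dataclass
class RegulatoryElement:
    element_id: str
    interval: GenomicInterval
    kind: str  # promoter | enhancer
    linked_genes: list[tuple[str, str]] = field(default_factory=list)  # (gene_id, source)


@dataclass(frozen=True, slots=True)
class BindingCall:
    tf_id: str
    element_id: str
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise InputError(f"binding probability {self.probability} outside [0, 1]")


@dataclass
class RegulatoryNetwork:
    """Layered TF -> element -> gene network with derived TF -> gene edges.

    ``tf_element`` maps (tf, element) -> max binding probability;
    ``element_genes`` maps element -> set of genes; ``tf_targets`` maps
    tf -> {gene: max supporting binding probability}. Out-degree counts
    distinct target genes, not edges.
    """

    tf_element: dict[tuple[str, str], float]
    element_genes: dict[str, set[str]]
    tf_targets: dict[str, dict[str, float]]
    hubs: set[str] = field(default_factory=set)

    @property
    def tfs(self) -> list[str]:
        return sorted(self.tf_targets)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for targets in self.tf_targets.values():
            out.update(targets)
        return out

    def out_degree(self, tf_id: str) -> int:
        return len(self.tf_targets.get(tf_id, ()))

    def n_tf_gene_edges(self) -> int:
        return sum(len(t) for t in self.tf_targets.values())


# ---------------------------------------------------------------------------
# Element definition
# ---------------------------------------------------------------------------


def define_promoters(
    genes: Sequence[GeneModel],
    upstream_bp: int = DEFAULT_PROMOTER_UPSTREAM,
    downstream_bp: int = 0,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[RegulatoryElement]:
    """One promoter per gene: the upstream_bp window ending at the TSS,
    strand-aware, clipped to chromosome bounds."""
    out = []
    for gene in genes:
        tss = gene.tss
        chrom = gene.interval.chrom
        chrom_len = chrom_lengths.get(chrom) if chrom_lengths else None
        if chrom_len is not None and tss >= chrom_len:
            raise InputError(
                f"TSS {tss} of {gene.gene_id} beyond chromosome {chrom} length {chrom_len}"
            )
        if gene.interval.strand == "-":
            # upstream of a minus-strand TSS extends to higher coordinates
            start = tss + 1 - downstream_bp
            end = tss + 1 + upstream_bp
        else:
            start = tss - upstream_bp
            end = tss + downstream_bp
            if end <= start:  # downstream_bp == 0: window ends at the TSS
                end = tss
        start = max(0, start)
        if chrom_len is not None:
            end = min(end, chrom_len)
        if end <= start:
            continue
        out.append(
            RegulatoryElement(
                element_id=f"prom_{gene.gene_id}",
                interval=GenomicInterval(chrom, start, end, gene.interval.strand),
                kind="promoter",
                linked_genes=[(gene.gene_id, "promoter")],
            )
        )
    return out


def classify_enhancers(
    candidates: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    min_gene_distance: int = DEFAULT_MIN_GENE_DISTANCE,
) -> list[RegulatoryElement]:
    """Keep candidates whose gap to the nearest gene span is >= min_gene_distance
    (inclusive); candidates overlapping or within the buffer are rejected."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    indexes = {
        chrom: IntervalIndex(
            [g.interval.start for g in gs], [g.interval.end for g in gs]
        )
        for chrom, gs in by_chrom.items()
    }
    out = []
    for i, cand in enumerate(candidates):
        idx = indexes.get(cand.chrom)
        if idx is not None:
            # a gene with gap < min_gene_distance falls in the buffered query
            buffered = idx.query(cand.start - min_gene_distance, cand.end + min_gene_distance)
            if buffered.size:
                continue
        out.append(
            RegulatoryElement(
                element_id=f"enh_{i}",
                interval=cand,
                kind="enhancer",
            )
        )
    return out


def activate_by_dhs(
    elements: Sequence[RegulatoryElement], dhs: Sequence[GenomicInterval]
) -> list[RegulatoryElement]:
    """Keep elements overlapping at least one open-chromatin (DHS) peak."""
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for peak in dhs:
        starts, ends = by_chrom.setdefault(peak.chrom, ([], []))
        starts.append(peak.start)
        ends.append(peak.end)
    indexes = {c: IntervalIndex(s, e) for c, (s, e) in by_chrom.items()}
    active = []
    for el in elements:
        idx = indexes.get(el.interval.chrom)
        if idx is not None and idx.query(el.interval.start, el.interval.end).size:
            active.append(el)
    n_prom = sum(1 for e in active if e.kind == "promoter")
    log.info(
        "DHS activation kept %d/%d elements (%d promoters, %d enhancers)",
        len(active), len(elements), n_prom, len(active) - n_prom,
    )
    return active


def link_enhancers_to_genes(
    enhancers: Sequence[RegulatoryElement],
    genes: Sequence[GeneModel],
    activity_signal,  # DataFrame: enhancer element_id x condition
    expression,  # DataFrame: gene_id x condition
    max_distance: int = DEFAULT_ENHANCER_WINDOW,
    alpha: float = 0.05,
) -> list[RegulatoryElement]:
    """Link each enhancer to nearby genes whose expression correlates with the
    enhancer's activity signal across conditions.

    Candidates are genes with TSS within max_distance; the Spearman
    correlation across shared conditions is tested and BH-corrected within
    each enhancer's candidate set. Links are written into ``linked_genes``.
    """
    shared = [c for c in activity_signal.columns if c in expression.columns]
    if len(shared) < 3:
        raise InputError(
            f"enhancer-gene correlation needs >= 3 shared conditions, got {len(shared)}"
        )
    act = activity_signal[shared]
    expr = expression[shared]
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.interval.chrom, []).append(g)
    out = []
    for enh in enhancers:
        enh = RegulatoryElement(enh.element_id, enh.interval, enh.kind, [])
        if enh.element_id in act.index:
            a = act.loc[enh.element_id].to_numpy(dtype=float)
            cand = [
                g
                for g in genes_by_chrom.get(enh.interval.chrom, [])
                if g.gene_id in expr.index
                and _tss_distance(enh.interval, g.tss) <= max_distance
            ]
            pvals, ids = [], []
            for g in cand:
                rho, p = spearman(a, expr.loc[g.gene_id].to_numpy(dtype=float))
                if not math.isnan(p):
                    pvals.append(p)
                    ids.append(g.gene_id)
            if pvals:
                q = bh_adjust(pvals)
                enh.linked_genes = [
                    (gid, "correlation") for gid, qv in zip(ids, q) if qv <= alpha
                ]
        out.append(enh)
    return out


def _tss_distance(interval: GenomicInterval, tss: int) -> int:
    if interval.start <= tss < interval.end:
        return 0
    return min(abs(tss - interval.start), abs(tss - (interval.end - 1)))


# ---------------------------------------------------------------------------
# Binding calls and assembly
# ---------------------------------------------------------------------------


def filter_binding(
    calls: Iterable[BindingCall], threshold: float = DEFAULT_BINDING_THRESHOLD
) -> list[BindingCall]:
    """Keep calls with probability >= threshold (inclusive); duplicate
    (tf, element) calls collapse to the maximum probability."""
    best: dict[tuple[str, str], float] = {}
    for call in calls:
        key = (call.tf_id, call.element_id)
        if call.probability > best.get(key, -1.0):
            best[key] = call.probability
    return [
        BindingCall(tf, el, p)
        for (tf, el), p in sorted(best.items())
        if p >= threshold
    ]


def assemble_network(
    binding: Iterable[BindingCall], elements: Sequence[RegulatoryElement]
) -> RegulatoryNetwork:
    """Union over elements of (TFs bound) x (genes linked) -> unique TF->gene
    edges, keeping the maximum supporting binding probability per edge."""
    element_genes = {el.element_id: {g for g, _ in el.linked_genes} for el in elements}
    tf_element: dict[tuple[str, str], float] = {}
    tf_targets: dict[str, dict[str, float]] = {}
    for call in binding:
        if call.element_id not in element_genes:
            raise InputError(f"binding call references unknown element {call.element_id}")
        key = (call.tf_id, call.element_id)
        tf_element[key] = max(tf_element.get(key, 0.0), call.probability)
    for (tf, el), prob in tf_element.items():
        targets = tf_targets.setdefault(tf, {})
        for gene in element_genes[el]:
            if prob > targets.get(gene, 0.0):
                targets[gene] = prob
    return RegulatoryNetwork(
        tf_element=tf_element, element_genes=element_genes, tf_targets=tf_targets
    )


def select_hubs(
    network: RegulatoryNetwork, fraction: float = DEFAULT_HUB_FRACTION
) -> set[str]:
    """Top floor(fraction x nTF) TFs by out-degree; ties at the cut broken by
    (out-degree desc, tf_id asc). The hub set is also stored on the network."""
    tfs = network.tfs
    if not any(network.out_degree(tf) > 0 for tf in tfs):
        raise InputError("hub selection needs >= 1 TF with out-degree > 0")
    n_hubs = math.floor(fraction * len(tfs))
    ranked = sorted(tfs, key=lambda tf: (-network.out_degree(tf), tf))
    hubs = set(ranked[:n_hubs])
    network.hubs = hubs
    return hubs


# ---------------------------------------------------------------------------
# ChIP-Seq evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class EdgeMetrics:
    sensitivity: float
    specificity: float
    precision: float
    f_score: float
    auroc: float
    auprc: float
    tp: int
    fp: int
    fn: int
    tn: int


def evaluate_against_chip(
    network: RegulatoryNetwork,
    tf_id: str,
    chip_peaks: Sequence[GenomicInterval],
    elements: Sequence[RegulatoryElement],
) -> EdgeMetrics:
    """Evaluate one TF's predicted targets against a ChIP-Seq gold standard.

    The gold standard is built by overlapping ChIP peaks with the elements
    and propagating to genes through the same element->gene links used by
    the network. The universe is every gene reachable from >= 1 element.
    AUROC/AUPRC rank genes by the maximum binding probability over the TF's
    supporting elements; genes without a predicted edge score 0.
    """
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for pk in chip_peaks:
        s, e = by_chrom.setdefault(pk.chrom, ([], []))
        s.append(pk.start)
        e.append(pk.end)
    indexes = {c: IntervalIndex(s, e) for c, (s, e) in by_chrom.items()}

    gold: set[str] = set()
    universe: set[str] = set()
    for el in elements:
        genes = {g for g, _ in el.linked_genes}
        universe.update(genes)
        idx = indexes.get(el.interval.chrom)
        if idx is not None and idx.query(el.interval.start, el.interval.end).size:
            gold.update(genes)
    if not gold:
        raise InputError(f"empty ChIP gold standard for {tf_id}")

    predicted = network.tf_targets.get(tf_id, {})
    genes = sorted(universe)
    y_true = np.array([g in gold for g in genes], dtype=bool)
    y_score = np.array([predicted.get(g, 0.0) for g in genes], dtype=float)
    y_pred = np.array([g in predicted for g in genes], dtype=bool)

    tp = int(np.sum(y_pred & y_true))
    fp = int(np.sum(y_pred & ~y_true))
    fn = int(np.sum(~y_pred & y_true))
    tn = int(np.sum(~y_pred & ~y_true))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return EdgeMetrics(
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f_score=f,
        auroc=_auroc(y_true, y_score),
        auprc=_auprc(y_true, y_score),
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
    )


def _auroc(y_true: np.ndarray, y_score: np.ndarray) -> float:
    n_pos = int(y_true.sum())
    n_neg = y_true.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return math.nan
    ranks = rank_avg(y_score)
    return float((ranks[y_true].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def rank_avg(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(x)


def _auprc(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """Area under the precision-recall curve by the step-wise (average
    precision) estimator over descending unique score thresholds."""
    n_pos = int(y_true.sum())
    if n_pos == 0:
        return math.nan
    order = np.argsort(-y_score, kind="stable")
    y = y_true[order]
    s = y_score[order]
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    # evaluate at the last index of each tied score block
    last = np.flatnonzero(np.diff(s, append=-np.inf) != 0)
    precision = tp[last] / (tp[last] + fp[last])
    recall = tp[last] / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


# ---------------------------------------------------------------------------
# Toy PWM scanner (feeds synthetic end-to-end runs; not a footprint model)
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


def pwm_scan(
    sequences: Mapping[str, str],
    pwms: Mapping[str, np.ndarray],
    score_threshold: float,
    max_non_acgt_fraction: float = 0.1,
) -> list[BindingCall]:
    """Scan labelled sequences with position weight matrices on both strands.

    Each PWM is a (length x 4) matrix of base probabilities (columns A,C,G,T;
    rows sum to 1). The per-window score is the log-odds versus a uniform
    background; the call probability is logistic(best_score - threshold), so
    a window at the threshold scores 0.5 and a strong consensus saturates
    toward 1. One call is emitted per (TF, sequence).
    """
    for tf, pwm in pwms.items():
        pwm = np.asarray(pwm, dtype=float)
        if pwm.ndim != 2 or pwm.shape[1] != 4:
            raise InputError(f"PWM {tf}: expected shape (L, 4)")
        if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
            raise InputError(f"PWM {tf}: rows must sum to 1")
    calls = []
    for seq_id, seq in sequences.items():
        seq = seq.upper()
        frac_bad = sum(1 for b in seq if b not in _BASES) / max(1, len(seq))
        if frac_bad > max_non_acgt_fraction:
            log.warning("sequence %s: %.0f%% non-ACGT bases", seq_id, 100 * frac_bad)
        rc = seq.translate(_COMP)[::-1]
        for tf, pwm in pwms.items():
            pwm = np.asarray(pwm, dtype=float)
            best = max(_best_window(seq, pwm), _best_window(rc, pwm))
            prob = 1.0 / (1.0 + math.exp(-(best - score_threshold)))
            calls.append(BindingCall(tf, seq_id, prob))
    return calls


def _best_window(seq: str, pwm: np.ndarray) -> float:
    L = pwm.shape[0]
    if len(seq) < L:
        return -math.inf
    logodds = np.log(np.maximum(pwm, 1e-9) / 0.25)
    idx = np.array([_BASES.find(b) for b in seq])
    best = -math.inf
    for i in range(len(seq) - L + 1):
        window = idx[i : i + L]
        if np.any(window < 0):
            continue
        best = max(best, float(logodds[np.arange(L), window].sum()))
    return best
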