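"""FSig-SNV: recurrence- and impact-weighted test for significantly mutated
coding and non-coding elements.

Each variant at position i contributes W_i x FS_i, where W_i is the
positional recurrence (number of distinct tumor samples mutated at that
exact position) and FS_i a non-negative functional-impact score. The
element score is the sum over the element's variants; because the sum runs
over variants, a position mutated in W samples contributes W^2 x FS
(the "variant" convention — the alternative "position" convention, summing
W x FS once per distinct position, is selectable).

Significance comes from a permutation null: for an element with n variants,
each null iterate draws n positional scores (a recurrence value resampled
from the class-wide per-position recurrence multiset, times a functional
score drawn from the class-wide score pool or from a per-position score
track evaluated at uniform positions within the element) and sums them.
P = (1 + #{X_n >= X_0}) / (N + 1), with Benjamini-Hochberg correction
applied separately within the CDS, promoter and enhancer classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .elements import ELEMENT_CLASSES, Element, ElementCatalog
from .genome_io import InputError, VariantSet
from .stats_core import bh_adjust, permutation_p  # noqa: F401  (re-exported test surface)

log = logging.getLogger(__name__)

DEFAULT_N_ITER = 1_000_000
DEFAULT_Q_MAX = 0.05

ScoreConvention = Literal["variant", "position"]
# per-position score track: (chrom, positions) -> FS array
Scorer = Callable[[str, np.ndarray], np.ndarray]


@dataclass
class ElementScore:
    element_id: str
    klass: str
    gene: str
    n_variants: int
    n_positions: int
    n_samples: int
    observed_score: float
    p_value: float
    q_value: float = np.nan
    significant: bool = False


@dataclass
class FsigSnvResult:
    scores: list[ElementScore]
    n_unassigned: int
    qq_tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "element_id": s.element_id,
                    "class": s.klass,
                    "gene": s.gene,
                    "n_variants": s.n_variants,
                    "n_positions": s.n_positions,
                    "n_samples": s.n_samples,
                    "score": s.observed_score,
                    "p": s.p_value,
                    "q": s.q_value,
                    "significant": s.significant,
                }
                for s in self.scores
            ]
        )


def positional_recurrence(variants: pd.DataFrame) -> dict[tuple[str, int], int]:
    """W(chrom, pos) = number of distinct samples mutated at that position."""
    if len(variants) == 0:
        return {}
    counts = (
        variants.drop_duplicates(["sample", "chrom", "pos"])
        .groupby(["chrom", "pos"], sort=False)
        .size()
    )
    return {(c, int(p)): int(w) for (c, p), w in counts.items()}


def element_score(
    w: np.ndarray, fs: np.ndarray, convention: ScoreConvention = "variant"
) -> float:
    """Observed element score from per-variant recurrence and impact arrays.

    ``variant``: sum over variants of W x FS (a W-recurrent position counts
    W times). ``position``: the same sum with each distinct position counted
    once — callers pass per-position arrays in that case.
    """
    w = np.asarray(w, dtype=float)
    fs = np.asarray(fs, dtype=float)
    if np.any(fs < 0):
        raise InputError("negative functional-impact score")
    return float(np.sum(w * fs))


def null_distribution(
    element: Element,
    n_variants: int,
    fs_pool: np.ndarray | None,
    w_pool: np.ndarray,
    n_iter: int,
    rng: np.random.Generator,
    scorer: Scorer | None = None,
) -> np.ndarray:
    """Null FSig scores: n_iter sums of n_variants resampled positional scores.

    FS values come from the per-position score track when a scorer is
    attached (evaluated at uniform positions within the element), otherwise
    from the class-wide empirical pool.
    """
    if n_iter < 1:
        raise InputError("n_iter must be >= 1 (p undefined otherwise)")
    if n_variants < 1:
        raise InputError("null distribution needs >= 1 variant")
    if w_pool.size == 0 or (scorer is None and (fs_pool is None or fs_pool.size == 0)):
        raise InputError("empty score pool")
    shape = (n_iter, n_variants)
    w = w_pool[rng.integers(0, w_pool.size, size=shape)]
    if scorer is not None:
        pos = rng.integers(element.interval.start, element.interval.end, size=shape)
        fs = scorer(element.interval.chrom, pos.ravel()).reshape(shape)
    else:
        fs = fs_pool[rng.integers(0, fs_pool.size, size=shape)]
    return (w * fs).sum(axis=1)


# adaptive early stopping: once this many exceedances have accrued and the
# running estimate is safely non-significant, further iterations cannot move
# the element below q = 0.05, so sampling stops. Reported p always uses the
# iterations actually run, so it remains a valid permutation p-value.
_EARLY_STOP_EXCEEDANCES = 200
_EARLY_STOP_MIN_P = 0.1
_BATCH = 2000


def _element_p(
    element: Element,
    observed: float,
    n_variants: int,
    fs_pool: np.ndarray | None,
    w_pool: np.ndarray,
    n_iter: int,
    rng: np.random.Generator,
    scorer: Scorer | None,
    adaptive: bool,
) -> float:
    done = 0
    exceed = 0
    while done < n_iter:
        batch = min(_BATCH, n_iter - done)
        null = null_distribution(element, n_variants, fs_pool, w_pool, batch, rng, scorer)
        exceed += int(np.sum(null >= observed))
        done += batch
        if adaptive and exceed >= _EARLY_STOP_EXCEEDANCES:
            if (1 + exceed) / (done + 1) > _EARLY_STOP_MIN_P:
                break
    return (1 + exceed) / (done + 1)


def qq_table(p_values: Sequence[float]) -> pd.DataFrame:
    """Observed vs expected -log10 p for a QQ plot."""
    p = np.sort(np.asarray(p_values, dtype=float))
    m = p.size
    expected = (np.arange(1, m + 1) - 0.5) / m
    return pd.DataFrame(
        {
            "expected_neglog10_p": -np.log10(expected),
            "observed_neglog10_p": -np.log10(p),
        }
    )


def run_fsig_snv(
    variants: VariantSet,
    catalog: ElementCatalog,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    q_max: float = DEFAULT_Q_MAX,
    convention: ScoreConvention = "variant",
    scorer: Scorer | None = None,
    fs_pool: Literal["class-wide"] = "class-wide",
    adaptive: bool = True,
) -> FsigSnvResult:
    """Score every element with >= 1 variant and test it against the
    permutation null; BH within each element class at q <= q_max.

    Variants must carry functional scores (``fs`` column) unless a scorer is
    attached, in which case scores are (re)computed from the score track.
    Variants outside all elements are counted and excluded.
    """
    df = variants.df.copy()
    if scorer is not None and len(df):
        fs_vals = np.empty(len(df))
        for chrom, sub in df.groupby("chrom", sort=False):
            fs_vals[sub.index.to_numpy()] = scorer(chrom, sub["pos"].to_numpy())
        df["fs"] = fs_vals
    if len(df) and df["fs"].isna().any():
        raise InputError("variants lack functional scores and no scorer is attached")
    if len(df) and (df["fs"] < 0).any():
        raise InputError("negative functional-impact score")

    w_map = positional_recurrence(df)
    df["w"] = [w_map[(c, int(p))] for c, p in zip(df["chrom"], df["pos"])] if len(df) else []

    # assign each variant to <= 1 element per class (first overlap wins)
    assignments: dict[str, dict[int, list[int]]] = {k: {} for k in ELEMENT_CLASSES}
    assigned_any = np.zeros(len(df), dtype=bool)
    for klass in ELEMENT_CLASSES:
        for row in df.itertuples():
            hits = catalog.query(klass, row.chrom, row.pos, row.pos + 1)
            if hits.size:
                assignments[klass].setdefault(int(hits[0]), []).append(row.Index)
                assigned_any[row.Index] = True
    n_unassigned = int((~assigned_any).sum())
    if n_unassigned:
        log.info("fsig-snv: %d variants outside all elements excluded", n_unassigned)

    # class-wide pools: per-position recurrence multiset + per-variant FS pool
    pools: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for klass in ELEMENT_CLASSES:
        idx = [i for rows in assignments[klass].values() for i in rows]
        sub = df.loc[idx]
        w_pool = (
            sub.drop_duplicates(["chrom", "pos"])["w"].to_numpy(dtype=float)
            if len(sub)
            else np.empty(0)
        )
        pools[klass] = (sub["fs"].to_numpy(dtype=float), w_pool)

    ss = np.random.SeedSequence(seed)
    scores: list[ElementScore] = []
    per_class_rows: dict[str, list[int]] = {k: [] for k in ELEMENT_CLASSES}
    ordered: list[tuple[str, int]] = [
        (klass, ei)
        for klass in ELEMENT_CLASSES
        for ei in sorted(assignments[klass])
    ]
    children = ss.spawn(len(ordered)) if ordered else []
    for (klass, ei), child in zip(ordered, children):
        element = catalog.elements[ei]
        rows = df.loc[assignments[klass][ei]]
        if convention == "variant":
            w = rows["w"].to_numpy(dtype=float)
            fs = rows["fs"].to_numpy(dtype=float)
            n_draw = len(rows)
        else:
            per_pos = rows.sort_values("fs", ascending=False).drop_duplicates(["chrom", "pos"])
            w = per_pos["w"].to_numpy(dtype=float)
            fs = per_pos["fs"].to_numpy(dtype=float)
            n_draw = len(per_pos)
        observed = element_score(w, fs, convention)
        fs_cls, w_cls = pools[klass]
        rng = np.random.default_rng(child)
        p = _element_p(element, observed, n_draw, fs_cls, w_cls, n_iter, rng, scorer, adaptive)
        per_class_rows[klass].append(len(scores))
        scores.append(
            ElementScore(
                element_id=element.element_id,
                klass=klass,
                gene=element.gene,
                n_variants=len(rows),
                n_positions=rows.drop_duplicates(["chrom", "pos"]).shape[0],
                n_samples=rows["sample"].nunique(),
                observed_score=observed,
                p_value=p,
            )
        )

    result = FsigSnvResult(scores=scores, n_unassigned=n_unassigned)
    for klass, rows_idx in per_class_rows.items():
        if not rows_idx:
            continue
        q = bh_adjust([scores[i].p_value for i in rows_idx])
        for i, qv in zip(rows_idx, q):
            scores[i].q_value = float(qv)
            scores[i].significant = qv <= q_max
        result.qq_tables[klass] = qq_table([scores[i].p_value for i in rows_idx])
    return result
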