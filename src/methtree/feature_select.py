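"""Marker-CpG screening: ANOVA -> Tukey-Kramer one-vs-all-others -> Boruta.

The cascade screens, per class, the CpG probes whose mean beta separates
that class from *every* other class (pairwise Tukey-Kramer adjusted
p < 0.01 and |delta-beta| above a threshold), after a cheap one-way ANOVA
pre-filter.  When a class cannot muster enough markers at delta-beta 0.2
the threshold is relaxed stepwise (0.15, then 0.1).  A Boruta run against
permuted shadow features then confirms the informative subset.

All matrix arguments are probes x samples DataFrames; ``labels`` is a
Series indexed by sample id (aligned to the matrix columns).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger("methtree")

DEFAULT_DELTA_SCHEDULE = (0.2, 0.15, 0.1)


def _group_stats(matrix: pd.DataFrame, labels: pd.Series):
    """Per-probe class means/counts and the pooled within-class variance.

    Returns (classes, counts, means [probes x k], mse [probes], df_within).
    """
    labels = labels.reindex(matrix.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some matrix samples")
    classes = np.array(sorted(labels.unique()))
    k = len(classes)
    if k < 2:
        raise ValueError("need at least 2 classes")
    X = matrix.to_numpy(dtype=float)
    counts = np.array([(labels == c).sum() for c in classes])
    means = np.empty((X.shape[0], k))
    ssw = np.zeros(X.shape[0])
    for j, c in enumerate(classes):
        cols = (labels == c).to_numpy()
        sub = X[:, cols]
        means[:, j] = sub.mean(axis=1)
        ssw += ((sub - means[:, [j]]) ** 2).sum(axis=1)
    df_within = int(counts.sum() - k)
    mse = ssw / df_within if df_within > 0 else np.full(X.shape[0], np.nan)
    return classes, counts, means, mse, df_within


# ---------------------------------------------------------------------------
# ANOVA screen
# ---------------------------------------------------------------------------

def anova_screen(matrix: pd.DataFrame, labels: pd.Series,
                 alpha: float = 0.05) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per probe; retain probes with p < alpha.

    Vectorized over probes.  Degenerate probes (zero within-class variance)
    get p = 0 when class means differ (perfect separation, retained) and
    p = 1 when they do not (no signal, excluded).

    Returns a DataFrame indexed by retained probe id with columns F, p.
    """
    classes, counts, means, mse, df_within = _group_stats(matrix, labels)
    k = len(classes)
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 samples for ANOVA")
    grand = (means * counts).sum(axis=1) / counts.sum()
    ssb = ((means - grand[:, None]) ** 2 * counts).sum(axis=1)
    msb = ssb / (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / mse
        p = stats.f.sf(F, k - 1, df_within)
    zero_within = mse <= 0
    equal_means = ssb <= 1e-30
    p = np.where(zero_within & equal_means, 1.0, p)
    p = np.where(zero_within & ~equal_means, 0.0, p)
    F = np.where(zero_within, np.where(equal_means, 0.0, np.inf), F)
    out = pd.DataFrame({"F": F, "p": p}, index=matrix.index)
    return out[out["p"] < alpha]


# ---------------------------------------------------------------------------
# Tukey-Kramer
# ---------------------------------------------------------------------------

def tukey_kramer(matrix: pd.DataFrame, labels: pd.Series, probe: str) -> pd.DataFrame:
    """All-pairs Tukey-Kramer comparison of class means at one probe.

    For classes (i, j): SE = sqrt((MSE / 2)(1/n_i + 1/n_j)), the observed
    studentized range q = |m_i - m_j| / SE, and the adjusted p is the upper
    tail of the studentized range distribution with k classes and N - k
    degrees of freedom (valid for unequal class sizes).
    """
    classes, counts, means, mse, df_within = _group_stats(matrix.loc[[probe]], labels)
    if (counts < 2).any():
        small = classes[counts < 2]
        raise ValueError(f"classes with < 2 samples: {list(small)}")
    k = len(classes)
    m = means[0]
    s2 = float(mse[0])
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = m[i] - m[j]
            if s2 <= 0:
                adj_p = 1.0 if diff == 0 else 0.0
            else:
                se = np.sqrt((s2 / 2.0) * (1.0 / counts[i] + 1.0 / counts[j]))
                q = abs(diff) / se
                adj_p = float(np.clip(
                    stats.studentized_range.sf(q, k, df_within), 0.0, 1.0))
            rows.append({"probe_id": probe, "class_a": classes[i],
                         "class_b": classes[j], "mean_diff": diff, "adj_p": adj_p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-vs-all-others marker selection
# ---------------------------------------------------------------------------

@dataclass
class MarkerPanel:
    """Per-class marker CpG lists with the delta level each was accepted at."""

    markers: dict[str, list[str]]
    accepted_delta: dict[str, float]
    p_threshold: float
    failures: list[str] = field(default_factory=list)

    @property
    def all_probes(self) -> list[str]:
        out: list[str] = []
        seen = set()
        for cls in sorted(self.markers):
            for p in self.markers[cls]:
                if p not in seen:
                    seen.add(p)
                    out.append(p)
        return out


def select_markers(matrix: pd.DataFrame, labels: pd.Series,
                   delta_schedule: Sequence[float] = DEFAULT_DELTA_SCHEDULE,
                   p_threshold: float = 0.01,
                   min_markers: int = 20) -> MarkerPanel:
    """One-vs-all-others marker selection with stepwise delta relaxation.

    A probe is a marker for class g at level delta iff for EVERY other
    class h the Tukey-Kramer adjusted p(g, h) is below ``p_threshold`` AND
    |m_g - m_h| > delta.  Each class uses the first level of the
    (strictly decreasing) schedule that yields at least ``min_markers``
    markers; a class that never reaches the quota keeps the last level's
    markers and is recorded as a failure.

    The adjusted-p comparison is carried out against the critical
    studentized-range quantile (one ``isf`` evaluation) rather than
    per-pair ``sf`` calls — the decisions are identical.
    """
    deltas = list(delta_schedule)
    if any(b >= a for a, b in zip(deltas, deltas[1:])):
        raise ValueError("delta_schedule must be strictly decreasing")
    classes, counts, means, mse, df_within = _group_stats(matrix, labels)
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 samples")
    k = len(classes)
    q_crit = float(stats.studentized_range.isf(p_threshold, k, df_within))

    # pairwise |diff| and significance, vectorized over probes
    diffs = means[:, :, None] - means[:, None, :]            # probes x k x k
    inv_n = 1.0 / counts
    se = np.sqrt((mse[:, None, None] / 2.0) * (inv_n[None, :, None] + inv_n[None, None, :]))
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.abs(diffs) / se
    degenerate = mse <= 0
    sig = q > q_crit
    if degenerate.any():
        # zero pooled variance: significant iff the means differ at all
        sig[degenerate] = np.abs(diffs[degenerate]) > 0

    markers: dict[str, list[str]] = {}
    accepted: dict[str, float] = {}
    failures: list[str] = []
    probe_ids = matrix.index.to_numpy()
    for gi, cls in enumerate(classes):
        others = [h for h in range(k) if h != gi]
        sig_all = sig[:, gi, others].all(axis=1)
        min_gap = np.abs(diffs[:, gi, others]).min(axis=1)
        chosen = None
        for delta in deltas:
            hit = sig_all & (min_gap > delta)
            if hit.sum() >= min_markers:
                chosen = delta
                break
        if chosen is None:
            chosen = deltas[-1]
            hit = sig_all & (min_gap > chosen)
            failures.append(str(cls))
            logger.warning(
                "class %s: only %d markers even at delta=%.3g (wanted %d)",
                cls, int(hit.sum()), chosen, min_markers)
        markers[str(cls)] = [str(p) for p in probe_ids[hit]]
        accepted[str(cls)] = float(chosen)
    return MarkerPanel(markers=markers, accepted_delta=accepted,
                       p_threshold=p_threshold, failures=failures)


def write_marker_panel(panel: MarkerPanel, path) -> None:
    rows = [
        {"class": cls, "probe_id": p, "accepted_delta": panel.accepted_delta[cls]}
        for cls in sorted(panel.markers) for p in panel.markers[cls]
    ]
    pd.DataFrame(rows, columns=["class", "probe_id", "accepted_delta"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Boruta confirmation
# ---------------------------------------------------------------------------

def boruta_confirm(features: pd.DataFrame, labels,
                   max_iter: int = 100, alpha: float = 0.05,
                   seed: int = 0, n_estimators: int = 300,
                   max_depth: int | None = 10,
                   keep_tentative: bool = False) -> list[str]:
    """Boruta all-relevant feature confirmation against shadow features.

    ``features`` is samples x features.  Each iteration appends a permuted
    ("shadow") copy of every still-active feature, fits a random-forest
    importance estimator, and scores an undecided feature a *hit* when its
    impurity importance exceeds the maximum shadow importance.  After each
    iteration every undecided feature's hit count is tested against
    Binomial(n_iterations, 1/2), two-sided with Bonferroni correction over
    the currently undecided features: significantly more hits confirms,
    significantly fewer rejects.  Stops when all features are decided or
    ``max_iter`` is reached; tentative features are dropped by default or
    resolved by the median-importance "rough fix" when ``keep_tentative``.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    cols = list(features.columns)
    if not cols:
        return []
    rng = np.random.default_rng(seed)
    X = features.to_numpy(dtype=float)

    undecided = set(range(len(cols)))
    confirmed: set[int] = set()
    hits = np.zeros(len(cols), dtype=int)
    imp_history: dict[int, list[float]] = {i: [] for i in range(len(cols))}
    shadow_max_history: list[float] = []

    for it in range(1, max_iter + 1):
        active = sorted(confirmed | undecided)
        if not undecided:
            break
        Xa = X[:, active]
        shadows = Xa.copy()
        for c in range(shadows.shape[1]):
            shadows[:, c] = rng.permutation(shadows[:, c])
        forest = RandomForestClassifier(
            n_estimators=n_estimators, max_depth=max_depth,
            class_weight="balanced", n_jobs=1,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        forest.fit(np.hstack([Xa, shadows]), y)
        imp = forest.feature_importances_
        real_imp = imp[: len(active)]
        shadow_max = float(imp[len(active):].max()) if len(active) else 0.0
        shadow_max_history.append(shadow_max)
        for pos, fi in enumerate(active):
            imp_history[fi].append(float(real_imp[pos]))
            if fi in undecided and real_imp[pos] > shadow_max:
                hits[fi] += 1

        todo = sorted(undecided)
        bonf = alpha / max(len(todo), 1)
        p_hi = stats.binom.sf(hits[todo] - 1, it, 0.5)
        p_lo = stats.binom.cdf(hits[todo], it, 0.5)
        p_two = np.clip(2.0 * np.minimum(p_hi, p_lo), 0.0, 1.0)
        for pos, fi in enumerate(todo):
            if p_two[pos] < bonf:
                if hits[fi] * 2 > it:
                    confirmed.add(fi)
                else:
                    pass  # rejected: simply drop from the active pool
                undecided.discard(fi)

    if undecided and keep_tentative:
        med_shadow = float(np.median(shadow_max_history))
        for fi in sorted(undecided):
            if np.median(imp_history[fi]) > med_shadow:
                confirmed.add(fi)
    elif undecided:
        logger.info("boruta: %d tentative feature(s) dropped at max_iter", len(undecided))

    return [cols[i] for i in sorted(confirmed)]
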