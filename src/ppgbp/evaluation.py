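"""Calibration schemes, rolling prediction, training strategies and the
metric / significance layer.

Two calibration schemes decide which of a subject's time-ordered samples
carry usable reference BP readings:

* **scheme_1** — the first 20% of the samples (23 of a typical 115), one
  initial calibration window, never refreshed;
* **scheme_2** — the first 4% (typically 5 samples) plus intermittent
  4-sample windows at ordinal positions 15–18, 35–38, 55–58, 75–78 and
  95–98 — roughly 20% of the samples as well, spread over the month.

Prediction is strictly rolling: a test sample may only be predicted from
calibration windows that lie entirely before it, so no future reference
reading ever leaks into training. Models are trained either on the target
subject's calibration samples alone (*individual*) or on those plus every
sample of all other subjects (*generalized*, leave-one-subject-out).

Sample indices are 1-based and inclusive throughout, matching the ordinal
convention ("the 15th–18th sample") the windows are defined in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .errors import InvalidArgumentError, TooFewSamplesError
from .ppgfeatures import FEATURE_SETS, FeatureSet
from .regressors import (
    DEFAULT_COMPONENTS,
    LWPLSQuery,
    _inv_covariance,
    gpr_fit,
    gpr_predict,
    lwpls_predict,
    pls_fit,
    pls_predict,
)

__all__ = [
    "SubjectDataset",
    "CalibrationScheme",
    "scheme1_indices",
    "scheme2_indices",
    "make_model_factory",
    "RollingResult",
    "rolling_predict",
    "assert_no_leakage",
    "interpolation_baseline",
    "compute_metrics",
    "compare_models",
    "similarity_histograms",
    "run_experiment",
    "EvalCell",
]

SCHEME2_FIXED_WINDOWS = ((15, 18), (35, 38), (55, 58), (75, 78), (95, 98))


@dataclass
class SubjectDataset:
    """Time-ordered usable samples for one subject.

    ``frame`` is indexed 1..n (contiguous), with feature columns plus
    ``sbp_ref`` and ``dbp_ref``. Rejected sessions are excluded before
    indexing, so ordinal calibration windows refer to retained samples.
    """

    subject_id: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if not (self.frame.index == np.arange(1, len(self.frame) + 1)).all():
            raise InvalidArgumentError("frame must be indexed 1..n contiguously")
        if "timestamp" in self.frame.columns:
            ts = pd.Series(self.frame["timestamp"].values)
            if not ts.is_monotonic_increasing:
                raise InvalidArgumentError("timestamps must be increasing")

    @property
    def n(self) -> int:
        return len(self.frame)

    @classmethod
    def from_feature_frame(cls, df: pd.DataFrame, subject_id: str) -> "SubjectDataset":
        sub = df[(df["subject_id"] == subject_id) & (~df["rejected"])].copy()
        sub = sub.sort_values("timestamp").reset_index(drop=True)
        sub.index = pd.RangeIndex(1, len(sub) + 1)
        return cls(subject_id=subject_id, frame=sub)


@dataclass
class CalibrationScheme:
    """A named set of disjoint, sorted 1-based inclusive index windows."""

    kind: str
    windows: list[tuple[int, int]]

    def __post_init__(self) -> None:
        prev_end = 0
        for a, b in self.windows:
            if a <= prev_end or b < a:
                raise InvalidArgumentError("windows must be disjoint and sorted")
            prev_end = b

    def indices(self) -> list[int]:
        out: list[int] = []
        for a, b in self.windows:
            out.extend(range(a, b + 1))
        return out


def scheme1_indices(n: int) -> CalibrationScheme:
    """Initial-calibration scheme: one window [1, round(0.2 n)] with
    round-half-up."""
    if n < 10:
        raise TooFewSamplesError(f"n = {n} < 10")
    k = int(math.floor(0.2 * n + 0.5))
    return CalibrationScheme(kind="scheme_1", windows=[(1, k)])


def scheme2_indices(n: int) -> CalibrationScheme:
    """Intermittent-calibration scheme: [1, ceil(0.04 n)] plus the fixed
    windows 15–18, 35–38, 55–58, 75–78, 95–98 (windows starting beyond n
    are dropped; a final window is clipped at n)."""
    if n < 18:
        raise TooFewSamplesError(f"n = {n} < 18")
    windows = [(1, int(math.ceil(0.04 * n)))]
    for a, b in SCHEME2_FIXED_WINDOWS:
        if a > n:
            break
        windows.append((a, min(b, n)))
    return CalibrationScheme(kind="scheme_2", windows=windows)


def scheme_for(kind: str, n: int) -> CalibrationScheme:
    if kind == "scheme_1":
        return scheme1_indices(n)
    if kind == "scheme_2":
        return scheme2_indices(n)
    raise InvalidArgumentError(f"unknown scheme kind {kind!r}")


# ---------------------------------------------------------------------------
# Model factories


def make_model_factory(
    model: str,
    D: int = DEFAULT_COMPONENTS,
    phi: float = 1.0,
    gpr_optimize: bool = True,
    gpr_maxiter: int = 50,
):
    """Return ``fit(X, y) -> predict(Xq) -> array`` for one of the three
    regressors (``"pls"``, ``"lwpls"``, ``"gpr"``).

    A single-sample training set (possible for scheme_2's initial window
    on very short records) degrades to a constant predictor at that
    sample's target: no regression is estimable from one reading.
    """
    model = model.lower()
    if model == "pls":

        def fit(X, y):
            m = pls_fit(X, y, D=max(1, min(D, X.shape[1], len(y) - 1)))
            return lambda Xq: np.atleast_1d(pls_predict(m, np.atleast_2d(Xq)))

    elif model == "lwpls":

        def fit(X, y):
            q = LWPLSQuery(
                Xt=X, yt=y, phi=phi, strict=False,
                D=max(1, min(D, X.shape[1], len(y) - 1)),
            )
            return lambda Xq: np.array(
                [lwpls_predict(q, row) for row in np.atleast_2d(Xq)]
            )

    elif model == "gpr":

        def fit(X, y):
            m = gpr_fit(X, y, optimize=gpr_optimize, maxiter=gpr_maxiter)
            return lambda Xq: np.atleast_1d(gpr_predict(m, np.atleast_2d(Xq)))

    else:
        raise InvalidArgumentError(f"unknown model {model!r}")

    def guarded_fit(X, y):
        if len(y) < 2:
            mean = float(np.mean(y))
            return lambda Xq: np.full(len(np.atleast_2d(Xq)), mean)
        return fit(X, y)

    return guarded_fit


# ---------------------------------------------------------------------------
# Rolling prediction


@dataclass
class RollingResult:
    """Predictions for all predictable test indices of one subject plus
    the bookkeeping needed for the no-leakage audit."""

    subject_id: str
    target: str
    predictions: pd.Series  # 1-based test indices -> predicted mmHg
    reference: pd.Series
    train_max_index: pd.Series  # per test index: highest own calibration index used
    unpredictable: list[int] = field(default_factory=list)


def _test_segments(n: int, scheme: CalibrationScheme) -> list[list[int]]:
    cal = set(scheme.indices())
    segments: list[list[int]] = []
    current: list[int] = []
    for i in range(1, n + 1):
        if i in cal:
            if current:
                segments.append(current)
                current = []
        else:
            current.append(i)
    if current:
        segments.append(current)
    return segments


def rolling_predict(
    ds: SubjectDataset,
    scheme: CalibrationScheme,
    model_factory,
    feature_names,
    target: str = "sbp_ref",
    strategy: str = "individual",
    others: list[SubjectDataset] | None = None,
) -> RollingResult:
    """Predict every non-calibration sample from strictly earlier
    calibration windows.

    For each contiguous test segment a fresh model is fit on the union of
    all calibration windows that end before the segment starts; under the
    generalized strategy all samples of every other subject are added to
    the training set. Test samples with no prior calibration window are
    reported as unpredictable, never imputed.
    """
    if strategy not in ("individual", "generalized"):
        raise InvalidArgumentError(f"unknown strategy {strategy!r}")
    if strategy == "generalized" and not others:
        raise InvalidArgumentError("generalized strategy requires other subjects")
    feature_names = list(feature_names)
    n = ds.n
    for a, b in scheme.windows:
        if b > n:
            raise InvalidArgumentError("scheme window exceeds dataset length")

    others_X = others_y = None
    if strategy == "generalized":
        frames = [o.frame for o in (others or [])]
        pooled = pd.concat(frames, axis=0)
        others_X = pooled[feature_names].to_numpy(dtype=float)
        others_y = pooled[target].to_numpy(dtype=float)

    preds: dict[int, float] = {}
    train_max: dict[int, int] = {}
    unpredictable: list[int] = []
    for segment in _test_segments(n, scheme):
        seg_start = segment[0]
        prior = [w for w in scheme.windows if w[1] < seg_start]
        if not prior:
            unpredictable.extend(segment)
            continue
        cal_idx = [i for a, b in prior for i in range(a, b + 1)]
        Xc = ds.frame.loc[cal_idx, feature_names].to_numpy(dtype=float)
        yc = ds.frame.loc[cal_idx, target].to_numpy(dtype=float)
        if strategy == "generalized":
            Xtr = np.vstack([Xc, others_X])
            ytr = np.concatenate([yc, others_y])
        else:
            Xtr, ytr = Xc, yc
        predict = model_factory(Xtr, ytr)
        Xq = ds.frame.loc[segment, feature_names].to_numpy(dtype=float)
        yhat = predict(Xq)
        hi = max(cal_idx)
        for i, v in zip(segment, np.asarray(yhat, dtype=float).ravel()):
            preds[i] = float(v)
            train_max[i] = hi

    idx = pd.Index(sorted(preds), name="sample")
    return RollingResult(
        subject_id=ds.subject_id,
        target=target,
        predictions=pd.Series([preds[i] for i in idx], index=idx),
        reference=ds.frame.loc[idx, target].astype(float),
        train_max_index=pd.Series([train_max[i] for i in idx], index=idx),
        unpredictable=unpredictable,
    )


def assert_no_leakage(result: RollingResult) -> None:
    """Raise if any test prediction used a calibration sample at or after
    its own index."""
    bad = result.train_max_index[result.train_max_index >= result.train_max_index.index]
    if len(bad):
        raise AssertionError(
            f"leakage for subject {result.subject_id} at indices {list(bad.index)[:5]}"
        )


def interpolation_baseline(
    ds: SubjectDataset, scheme: CalibrationScheme, target: str = "sbp_ref"
) -> RollingResult:
    """Reference-only baseline for the intermittent scheme: each
    inter-window test segment is predicted by linear interpolation (in
    sample index) between the mean reference BP of the two flanking
    windows, anchored at the windows' centre indices; segments after the
    last window carry the last window's mean forward."""
    if len(scheme.windows) < 2:
        raise InvalidArgumentError("interpolation baseline needs at least two windows")
    centers = [(a + b) / 2.0 for a, b in scheme.windows]
    means = [
        float(ds.frame.loc[list(range(a, b + 1)), target].mean())
        for a, b in scheme.windows
    ]
    preds: dict[int, float] = {}
    train_max: dict[int, int] = {}
    for segment in _test_segments(ds.n, scheme):
        seg_start = segment[0]
        left = max(
            (k for k, w in enumerate(scheme.windows) if w[1] < seg_start),
            default=None,
        )
        if left is None:
            continue  # before any window: no anchor, unpredictable
        if left + 1 < len(scheme.windows):
            c0, c1 = centers[left], centers[left + 1]
            m0, m1 = means[left], means[left + 1]
            for i in segment:
                preds[i] = m0 + (m1 - m0) * (i - c0) / (c1 - c0)
                train_max[i] = scheme.windows[left + 1][1]
        else:
            for i in segment:
                preds[i] = means[left]
                train_max[i] = scheme.windows[left][1]
    idx = pd.Index(sorted(preds), name="sample")
    return RollingResult(
        subject_id=ds.subject_id,
        target=target,
        predictions=pd.Series([preds[i] for i in idx], index=idx),
        reference=ds.frame.loc[idx, target].astype(float),
        train_max_index=pd.Series([train_max[i] for i in idx], index=idx),
        unpredictable=[],
    )


# ---------------------------------------------------------------------------
# Metrics and significance


def compute_metrics(pred, ref) -> dict[str, float | None]:
    """Error metrics for one (model, subject, target) cell.

    error = pred - ref; reports MAE, mean error (ME), SD of the error
    (n-1 denominator), RMSE, Pearson r (None when either side is
    constant) and the Bland–Altman limits ME ± 1.96 SD.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if pred.size != ref.size:
        raise InvalidArgumentError("pred and ref lengths differ")
    if pred.size < 2:
        raise InvalidArgumentError("need at least two samples for metrics")
    err = pred - ref
    mae = float(np.mean(np.abs(err)))
    me = float(np.mean(err))
    sd = float(np.std(err, ddof=1))
    rmse = float(np.sqrt(np.mean(err**2)))
    if np.std(pred) < 1e-12 or np.std(ref) < 1e-12:
        r = None
    else:
        r = float(spstats.pearsonr(pred, ref)[0])
    return {
        "mae": mae,
        "me": me,
        "sd": sd,
        "rmse": rmse,
        "pearson_r": r,
        "ba_low": me - 1.96 * sd,
        "ba_high": me + 1.96 * sd,
        "n": int(pred.size),
    }


def compare_models(maes_a, maes_b) -> dict:
    """Paired two-sided Student t-test across subjects on per-subject
    MAEs; reports which side is lower on average."""
    a = np.asarray(maes_a, dtype=float)
    b = np.asarray(maes_b, dtype=float)
    if a.size != b.size:
        raise InvalidArgumentError("per-subject MAE lists differ in length")
    if np.allclose(a, b):
        t, p = 0.0, 1.0
    else:
        t, p = spstats.ttest_rel(a, b)
    return {
        "t": float(t),
        "p": float(p),
        "lower": "A" if a.mean() <= b.mean() else "B",
        "small_sample": bool(a.size < 5),
    }


def similarity_histograms(
    df: pd.DataFrame,
    feature_names=("hr", "a02", "a25", "ri"),
    phi: float = 1.0,
    max_pairs: int = 100_000,
    seed: int = 0,
) -> dict:
    """Intra- vs inter-subject similarity distributions in feature space.

    Similarity between two samples is ``exp(-d / (sigma_d * phi))`` with d
    their Mahalanobis distance under the pooled feature covariance and
    sigma_d the SD of all sampled distances — the same distance-to-
    similarity map the locally weighted model uses. Pairs are subsampled
    to at most ``max_pairs`` per group, seeded.
    """
    feature_names = list(feature_names)
    use = df[~df.get("rejected", pd.Series(False, index=df.index))]
    X = use[feature_names].to_numpy(dtype=float)
    labels = use["subject_id"].to_numpy()
    if np.unique(labels).size < 2:
        raise InvalidArgumentError("need at least two subjects for inter-similarity")
    Si = _inv_covariance(np.cov(X, rowvar=False))
    rng = np.random.default_rng(seed)
    n = X.shape[0]

    def sample_pairs(same: bool) -> np.ndarray:
        ii = rng.integers(0, n, size=4 * max_pairs)
        jj = rng.integers(0, n, size=4 * max_pairs)
        keep = ii != jj
        match = labels[ii] == labels[jj]
        keep &= match if same else ~match
        ii, jj = ii[keep][:max_pairs], jj[keep][:max_pairs]
        diff = X[ii] - X[jj]
        return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", diff, Si, diff), 0.0))

    d_intra = sample_pairs(True)
    d_inter = sample_pairs(False)
    sigma = float(np.concatenate([d_intra, d_inter]).std(ddof=0))
    if sigma < 1e-12:  # all pairs equidistant (e.g. identical features)
        s_intra = np.ones_like(d_intra)
        s_inter = np.ones_like(d_inter)
    else:
        s_intra = np.exp(-d_intra / (sigma * phi))
        s_inter = np.exp(-d_inter / (sigma * phi))
    return {
        "intra": s_intra,
        "inter": s_inter,
        "median_intra": float(np.median(s_intra)),
        "median_inter": float(np.median(s_inter)),
    }


# ---------------------------------------------------------------------------
# Full factorial experiment


@dataclass
class EvalCell:
    """One (model, feature set, scheme, strategy, target) cell: per-subject
    metric rows plus pooled metrics over concatenated test errors."""

    model: str
    feature_set: str
    scheme: str
    strategy: str
    target: str
    per_subject: pd.DataFrame
    pooled: dict


TARGET_COLUMNS = {"sbp": "sbp_ref", "dbp": "dbp_ref"}


def evaluate_cell(
    datasets: list[SubjectDataset],
    model: str,
    feature_set: FeatureSet,
    scheme_kind: str,
    strategy: str,
    target: str,
    D: int = DEFAULT_COMPONENTS,
    phi: float = 1.0,
    gpr_optimize: bool = True,
    gpr_maxiter: int = 50,
    audit: bool = True,
) -> EvalCell:
    """Evaluate one factorial cell over all subjects."""
    feature_names = list(FEATURE_SETS[FeatureSet(feature_set)])
    col = TARGET_COLUMNS[target]
    factory = make_model_factory(
        model, D=D, phi=phi, gpr_optimize=gpr_optimize, gpr_maxiter=gpr_maxiter
    )
    rows = []
    all_pred, all_ref = [], []
    for k, ds in enumerate(datasets):
        scheme = scheme_for(scheme_kind, ds.n)
        others = [d for j, d in enumerate(datasets) if j != k] if strategy == "generalized" else None
        res = rolling_predict(
            ds, scheme, factory, feature_names, target=col,
            strategy=strategy, others=others,
        )
        if audit:
            assert_no_leakage(res)
        m = compute_metrics(res.predictions.values, res.reference.values)
        m["subject_id"] = ds.subject_id
        m["n_unpredictable"] = len(res.unpredictable)
        rows.append(m)
        all_pred.append(res.predictions.values)
        all_ref.append(res.reference.values)
    pooled = compute_metrics(np.concatenate(all_pred), np.concatenate(all_ref))
    return EvalCell(
        model=model, feature_set=FeatureSet(feature_set).value,
        scheme=scheme_kind, strategy=strategy, target=target,
        per_subject=pd.DataFrame(rows).set_index("subject_id"),
        pooled=pooled,
    )


def run_experiment(
    datasets: list[SubjectDataset],
    models=("pls", "lwpls", "gpr"),
    feature_sets=(FeatureSet.SET1, FeatureSet.SET2, FeatureSet.SET3),
    schemes=("scheme_1", "scheme_2"),
    strategies=("individual", "generalized"),
    targets=("sbp", "dbp"),
    **model_kwargs,
) -> tuple[pd.DataFrame, list[EvalCell]]:
    """Full factorial evaluation grid.

    Returns a tidy DataFrame (one row per cell per subject plus a pooled
    row per cell) and the list of :class:`EvalCell` objects. The
    generalized strategy is leave-one-subject-out: the held-out subject's
    own calibration samples are merged with all samples of the others.
    """
    if not (len(models) and len(feature_sets) and len(schemes)
            and len(strategies) and len(targets)):
        raise InvalidArgumentError("empty factor list")
    cells: list[EvalCell] = []
    rows = []
    for model in models:
        for fset in feature_sets:
            for scheme in schemes:
                for strategy in strategies:
                    for target in targets:
                        cell = evaluate_cell(
                            datasets, model, fset, scheme, strategy, target,
                            **model_kwargs,
                        )
                        cells.append(cell)
                        base = {
                            "model": cell.model, "feature_set": cell.feature_set,
                            "scheme": cell.scheme, "strategy": cell.strategy,
                            "target": cell.target,
                        }
                        for sid, r in cell.per_subject.iterrows():
                            rows.append({**base, "subject_id": sid, **r.to_dict()})
                        rows.append({**base, "subject_id": "pooled", **cell.pooled})
    return pd.DataFrame(rows), cells


def rank_report(cells: list[EvalCell]) -> str:
    """Plain-text ranking of cells by pooled MAE with pairwise t-test
    markers against the best cell per (target, scheme, strategy) block."""
    lines = ["Model ranking by pooled MAE (mmHg)", "=" * 40]
    frame = pd.DataFrame(
        [
            {
                "model": c.model, "set": c.feature_set, "scheme": c.scheme,
                "strategy": c.strategy, "target": c.target,
                "mae": c.pooled["mae"], "cell": c,
            }
            for c in cells
        ]
    )
    for (target, scheme, strategy), grp in frame.groupby(
        ["target", "scheme", "strategy"]
    ):
        grp = grp.sort_values("mae")
        best = grp.iloc[0]
        lines.append(f"\n[{target.upper()} | {scheme} | {strategy}]")
        for _, row in grp.iterrows():
            mark = ""
            if row["cell"] is not best["cell"]:
                cmp = compare_models(
                    best["cell"].per_subject["mae"], row["cell"].per_subject["mae"]
                )
                if cmp["p"] < 0.001:
                    mark = " **"
                elif cmp["p"] < 0.05:
                    mark = " *"
            lines.append(
                f"  {row['model']:>6s}_{row['set']}: MAE {row['mae']:6.2f}{mark}"
            )
    lines.append("\n(* p<0.05, ** p<0.001 vs the block's best, paired t-test)")
    return "\n".join(lines)
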