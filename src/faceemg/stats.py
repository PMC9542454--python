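"""Nonparametric group statistics for the facial-sEMG affect analysis.

Covers the full inferential surface of the study design:

- manipulation check: per-category rating summaries, Friedman omnibus test
  across the three video categories, pairwise Wilcoxon follow-ups;
- paired amplitude comparisons per sensing modality (five sensors plus their
  average) with Bonferroni familywise correction (m = 6 for the rating-bin
  analyses, m = 18 = 3 pairs x 6 modalities for the video-type analysis) and
  star annotations;
- segmented Pearson correlations between amplitude and valence level
  (negative-to-neutral [1-5], neutral-to-positive [5-9], full range [1-9]);
- a second-order (quadratic) trend fit quantifying the V-shaped relation of
  amplitude to valence.

Sign convention for paired tests: ``wilcoxon_paired(x, y)`` ranks ``x - y``,
so ``z > 0`` means the first operand tends to exceed the second.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import amplitude as amp_mod
from . import epochs as epochs_mod
from . import preprocess as prep_mod
from .epochs import SCHEME_CONDITIONS, SCHEMES
from .types import (
    CHANNELS,
    SENSORS_AVERAGE,
    DegenerateComparisonError,
    RatingRecord,
    SessionSchedule,
)

__all__ = [
    "FriedmanResult",
    "PairedTestResult",
    "CorrelationResult",
    "TrendFit",
    "friedman",
    "wilcoxon_paired",
    "bonferroni_adjust",
    "annotate",
    "paired_amplitude_analysis",
    "manipulation_check",
    "segment_pearson",
    "quadratic_trend",
    "cohort_analysis",
    "CohortResults",
    "write_results",
]

#: The six sensing modalities of every amplitude analysis.
MODALITIES: tuple[str, ...] = CHANNELS + (SENSORS_AVERAGE,)

#: Condition pairs tested per scheme (first minus second).
SCHEME_PAIRS = {
    "valence_bin": (("V_negative", "V_positive"),),
    "arousal_bin": (("A_low", "A_high"),),
    "video_type": (
        ("W_neutral", "W_positive"),
        ("W_neutral", "W_negative"),
        ("W_negative", "W_positive"),
    ),
}

#: Valence segments of the V-shape quantification.
SEGMENTS = ((1, 5), (5, 9), (1, 9))


@dataclass(frozen=True)
class FriedmanResult:
    chi2: float
    df: int
    p: float
    mean_ranks: dict[str, float]


@dataclass(frozen=True)
class PairedTestResult:
    n_pairs: int
    statistic: float  # W+: rank sum of positive differences
    z: float
    p_raw: float
    p_adj: float
    annotation: str

    def adjusted(self, m: int) -> "PairedTestResult":
        p_adj = bonferroni_adjust(self.p_raw, m)
        return replace(self, p_adj=p_adj, annotation=annotate(p_adj))


@dataclass(frozen=True)
class CorrelationResult:
    segment: tuple[int, int]
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class TrendFit:
    """Least-squares quadratic fit y = a*x^2 + b*x + c.

    A positive quadratic coefficient ``a`` indicates a V/U shape. Standard
    errors and the 95% confidence half-widths are NaN when the fit has no
    residual degrees of freedom.
    """

    quadratic: float
    linear: float
    intercept: float
    se: tuple[float, float, float]
    ci95_halfwidth: tuple[float, float, float]
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.quadratic * x**2 + self.linear * x + self.intercept


def friedman(matrix: np.ndarray, condition_names: Sequence[str] | None = None
             ) -> FriedmanResult:
    """Friedman rank test on an ``n_subjects x k_conditions`` matrix.

    Uses within-subject mid-ranks and the standard tie-corrected chi-square
    statistic with ``k - 1`` degrees of freedom. An all-tied matrix yields
    chi2 = 0, p = 1.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x conditions)")
    n, k = matrix.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 conditions, got {n} x {k}")
    if np.isnan(matrix).any():
        raise ValueError("matrix has missing cells")
    ranks = np.apply_along_axis(sstats.rankdata, 1, matrix)
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in matrix:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts**3 - counts)
    c = 1.0 - ties / (n * k * (k**2 - 1))
    if c <= 0:
        chi2 = 0.0
    else:
        chi2 /= c
    chi2 = max(0.0, float(chi2))
    df = k - 1
    p = float(sstats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    if condition_names is None:
        condition_names = [f"c{j + 1}" for j in range(k)]
    mean_ranks = {name: float(m) for name, m in zip(condition_names,
                                                    ranks.mean(axis=0))}
    return FriedmanResult(chi2=chi2, df=df, p=p, mean_ranks=mean_ranks)


def wilcoxon_paired(
    x: np.ndarray, y: np.ndarray, zero_method: str = "wilcox"
) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Normal approximation with tie-corrected variance and no continuity
    correction; ``z > 0`` when ``x`` tends to exceed ``y``. Zero differences
    are discarded (``zero_method="wilcox"``, the common default) or handled
    by Pratt's method (``"pratt"``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    d = x - y
    if np.all(d == 0):
        raise DegenerateComparisonError(
            "all paired differences are zero; comparison is degenerate"
        )
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    n_zero = int(np.sum(d == 0))
    if zero_method == "wilcox":
        d = d[d != 0]
        n_zero = 0
    n = d.size
    if n - n_zero < 5:
        raise DegenerateComparisonError(
            f"only {n - n_zero} nonzero paired differences (< 5); "
            "comparison is degenerate"
        )
    ranks = sstats.rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    mn = 0.25 * (n * (n + 1) - n_zero * (n_zero + 1))
    var = (n * (n + 1) * (2 * n + 1)
           - n_zero * (n_zero + 1) * (2 * n_zero + 1)) / 24.0
    nonzero_ranks = ranks[d != 0]
    _, counts = np.unique(nonzero_ranks, return_counts=True)
    var -= np.sum(counts**3 - counts) / 48.0
    if var <= 0:
        raise DegenerateComparisonError("zero variance in signed ranks")
    z = (w_plus - mn) / np.sqrt(var)
    p = float(2.0 * sstats.norm.sf(abs(z)))
    p = min(1.0, p)
    return PairedTestResult(
        n_pairs=int(x.size),
        statistic=w_plus,
        z=float(z),
        p_raw=p,
        p_adj=p,
        annotation=annotate(p),
    )


def bonferroni_adjust(p_raw: float, m: int) -> float:
    """Familywise Bonferroni adjustment: ``min(1, m * p)``."""
    if not 0 <= p_raw <= 1:
        raise ValueError(f"p_raw must be in [0, 1], got {p_raw}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return min(1.0, m * p_raw)


def annotate(p_adj: float) -> str:
    """Star annotation: ns above 0.05, then one star per decade of p down to
    four stars at p <= 1e-4."""
    if not 0 <= p_adj <= 1:
        raise ValueError(f"p must be in [0, 1], got {p_adj}")
    if p_adj > 0.05:
        return "ns"
    if p_adj > 1e-2:
        return "*"
    if p_adj > 1e-3:
        return "**"
    if p_adj > 1e-4:
        return "***"
    return "****"


def paired_amplitude_analysis(
    means: pd.DataFrame, scheme: str, zero_method: str = "wilcox"
) -> pd.DataFrame:
    """Wilcoxon paired comparisons of condition means per sensing modality.

    Rating-bin schemes test one pair over 6 modalities (m = 6); the
    video-type scheme tests 3 category pairs over 6 modalities (m = 18).
    Subjects missing either member of a pair are dropped pairwise. A cell
    with fewer than 5 complete pairs is recorded as a degenerate row (NaN
    statistics) rather than silently dropped, keeping the table structurally
    complete.
    """
    if scheme not in SCHEME_PAIRS:
        raise ValueError(
            f"unknown scheme {scheme!r}; valid: {list(SCHEME_PAIRS)}"
        )
    pairs = SCHEME_PAIRS[scheme]
    m = len(pairs) * len(MODALITIES)
    wide = means.pivot_table(
        index=["subject_id", "channel"], columns="condition", values="value",
        aggfunc="first",
    )
    rows = []
    for channel in MODALITIES:
        try:
            sub = wide.xs(channel, level="channel")
        except KeyError:
            sub = pd.DataFrame()
        for cond_a, cond_b in pairs:
            row: dict = {
                "channel": channel,
                "condition_a": cond_a,
                "condition_b": cond_b,
                "m": m,
            }
            if cond_a in sub.columns and cond_b in sub.columns:
                paired = sub[[cond_a, cond_b]].dropna()
            else:
                paired = pd.DataFrame(columns=[cond_a, cond_b])
            try:
                if len(paired) < 5:
                    raise DegenerateComparisonError(
                        f"only {len(paired)} complete pairs"
                    )
                res = wilcoxon_paired(
                    paired[cond_a].to_numpy(), paired[cond_b].to_numpy(),
                    zero_method=zero_method,
                ).adjusted(m)
                row.update(
                    n_pairs=res.n_pairs,
                    mean_a=float(paired[cond_a].mean()),
                    mean_b=float(paired[cond_b].mean()),
                    statistic=res.statistic,
                    z=res.z,
                    p_raw=res.p_raw,
                    p_adj=res.p_adj,
                    annotation=res.annotation,
                )
            except DegenerateComparisonError as exc:
                row.update(
                    n_pairs=len(paired),
                    mean_a=np.nan, mean_b=np.nan, statistic=np.nan, z=np.nan,
                    p_raw=np.nan, p_adj=np.nan, annotation="degenerate",
                )
                row["note"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ManipulationCheck:
    """Did the video categories induce the intended affect?

    ``table`` summarizes raw ratings per category (mean +/- SD over all
    individual ratings, the scale on which such tables are usually printed);
    the Friedman and Wilcoxon tests run on per-subject per-category mean
    ratings. Pairwise follow-ups are reported (uncorrected) only when the
    omnibus test is significant at 0.05.
    """

    table: pd.DataFrame
    friedman: dict[str, FriedmanResult]
    pairwise: dict[str, pd.DataFrame | None]
    subject_means: dict[str, pd.DataFrame]


def manipulation_check(
    ratings: Iterable[RatingRecord],
    category_map: dict[str, str] | SessionSchedule,
) -> ManipulationCheck:
    if isinstance(category_map, SessionSchedule):
        category_map = {ev.video_id: ev.category for ev in category_map.events}
    df = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "video_id": r.video_id,
                "valence": r.valence,
                "arousal": r.arousal,
            }
            for r in ratings
        ]
    )
    missing = sorted(set(df["video_id"]) - set(category_map))
    if missing:
        raise ValueError(f"videos without a category: {missing}")
    df["category"] = df["video_id"].map(category_map)

    table = (
        df.melt(
            id_vars=["subject_id", "category"],
            value_vars=["valence", "arousal"],
            var_name="scale",
        )
        .groupby(["category", "scale"])["value"]
        .agg(mean="mean", sd="std", n="size")
        .reset_index()
    )

    categories = ("neutral", "negative", "positive")
    friedman_res: dict[str, FriedmanResult] = {}
    pairwise: dict[str, pd.DataFrame | None] = {}
    subject_means: dict[str, pd.DataFrame] = {}
    for scale in ("valence", "arousal"):
        wide = (
            df.pivot_table(index="subject_id", columns="category",
                           values=scale, aggfunc="mean")
            .reindex(columns=categories)
        )
        complete = wide.dropna()
        dropped = len(wide) - len(complete)
        if dropped:
            import logging

            logging.getLogger(__name__).warning(
                "%d subject(s) missing a category dropped from the %s "
                "manipulation check", dropped, scale,
            )
        subject_means[scale] = complete
        friedman_res[scale] = friedman(complete.to_numpy(), categories)
        if friedman_res[scale].p < 0.05:
            rows = []
            for a, b in (("neutral", "negative"), ("positive", "negative"),
                         ("positive", "neutral")):
                try:
                    res = wilcoxon_paired(complete[a].to_numpy(),
                                          complete[b].to_numpy())
                    rows.append(
                        {
                            "condition_a": a,
                            "condition_b": b,
                            "n_pairs": res.n_pairs,
                            "z": res.z,
                            "p": res.p_raw,
                            "annotation": res.annotation,
                        }
                    )
                except DegenerateComparisonError as exc:
                    rows.append(
                        {
                            "condition_a": a,
                            "condition_b": b,
                            "n_pairs": len(complete),
                            "z": np.nan,
                            "p": np.nan,
                            "annotation": "degenerate",
                            "note": str(exc),
                        }
                    )
            pairwise[scale] = pd.DataFrame(rows)
        else:
            pairwise[scale] = None
    return ManipulationCheck(
        table=table, friedman=friedman_res, pairwise=pairwise,
        subject_means=subject_means,
    )


def segment_pearson(
    levels: np.ndarray, values: np.ndarray, lo: int, hi: int
) -> CorrelationResult:
    """Pearson correlation over points whose rating level lies in [lo, hi]
    (both ends inclusive)."""
    levels = np.asarray(levels, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = (levels >= lo) & (levels <= hi)
    xs, ys = levels[mask], values[mask]
    if xs.size < 3:
        raise ValueError(
            f"need >= 3 points in segment [{lo}, {hi}], got {xs.size}"
        )
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise DegenerateComparisonError(
            f"zero variance in segment [{lo}, {hi}]; correlation undefined"
        )
    res = sstats.pearsonr(xs, ys)
    return CorrelationResult(
        segment=(lo, hi), r=float(res.statistic), p=float(res.pvalue),
        n=int(xs.size),
    )


def quadratic_trend(levels: np.ndarray, values: np.ndarray) -> TrendFit:
    """Least-squares second-order fit of amplitude against rating level."""
    x = np.asarray(levels, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError(f"need >= 4 points, got {x.size}")
    if np.unique(x).size < 3:
        raise ValueError(
            f"need >= 3 distinct levels for a quadratic fit, got "
            f"{np.unique(x).size}"
        )
    V = np.column_stack([x**2, x, np.ones_like(x)])
    beta, *_ = np.linalg.lstsq(V, y, rcond=None)
    resid = y - V @ beta
    dof = x.size - 3
    if dof > 0:
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(V.T @ V)
        se = np.sqrt(np.diag(cov))
        tcrit = sstats.t.ppf(0.975, dof)
        ci = tcrit * se
    else:
        se = np.full(3, np.nan)
        ci = np.full(3, np.nan)
    return TrendFit(
        quadratic=float(beta[0]),
        linear=float(beta[1]),
        intercept=float(beta[2]),
        se=tuple(float(v) for v in se),
        ci95_halfwidth=tuple(float(v) for v in ci),
        n=int(x.size),
    )


@dataclass
class CohortResults:
    """Tidy result bundle of a full cohort analysis."""

    per_video: pd.DataFrame
    condition_means: dict[str, pd.DataFrame]
    paired: dict[str, pd.DataFrame]
    manipulation: ManipulationCheck
    correlations: pd.DataFrame
    trends: pd.DataFrame
    n_subjects: int

    def summary(self) -> str:
        out = io.StringIO()
        w = out.write
        w(f"Cohort analysis ({self.n_subjects} subjects)\n")
        w("=" * 44 + "\n\n")
        w("Manipulation check (ratings per video category)\n")
        for _, row in self.manipulation.table.iterrows():
            w(f"  {row['category']:<9} {row['scale']:<8} "
              f"{row['mean']:5.2f} +/- {row['sd']:4.2f}  (n={int(row['n'])})\n")
        for scale, fr in self.manipulation.friedman.items():
            w(f"  Friedman ({scale}): chi2({fr.df}) = {fr.chi2:.2f}, "
              f"p = {fr.p:.2e}; mean ranks "
              + ", ".join(f"{k}={v:.2f}" for k, v in fr.mean_ranks.items())
              + "\n")
            pw = self.manipulation.pairwise[scale]
            if pw is not None:
                for _, r in pw.iterrows():
                    w(f"    {r['condition_a']} vs {r['condition_b']}: "
                      f"z = {r['z']:.3f}, p = {r['p']:.2e} {r['annotation']}\n")
        for scheme, table in self.paired.items():
            w(f"\nPaired Wilcoxon tests ({scheme}, Bonferroni m = "
              f"{int(table['m'].iloc[0])})\n")
            for _, r in table.iterrows():
                if r["annotation"] == "degenerate":
                    w(f"  {r['channel']:<16} {r['condition_a']} vs "
                      f"{r['condition_b']}: degenerate\n")
                else:
                    w(f"  {r['channel']:<16} {r['condition_a']} vs "
                      f"{r['condition_b']}: mean {r['mean_a']:.3f} vs "
                      f"{r['mean_b']:.3f}, z = {r['z']:+.3f}, "
                      f"p_adj = {r['p_adj']:.2e} {r['annotation']}\n")
        w("\nSegmented Pearson correlations (amplitude vs valence level)\n")
        for _, r in self.correlations.iterrows():
            w(f"  {r['channel']:<16} [{int(r['seg_lo'])}-{int(r['seg_hi'])}]: "
              f"r = {r['r']:+.2f} (p = {r['p']:.2e}, n = {int(r['n'])}) "
              f"{annotate(r['p'])}\n")
        w("\nQuadratic trend (amplitude vs valence level)\n")
        for _, r in self.trends.iterrows():
            w(f"  {r['channel']:<16} curvature = {r['quadratic']:+.4f} "
              f"(se = {r['se_quadratic']:.4f}), linear = {r['linear']:+.4f}, "
              f"n = {int(r['n'])}\n")
        return out.getvalue()


def cohort_analysis(
    cohort,
    method: str = "rms",
    window_s: float = amp_mod.DEFAULT_WINDOW_S,
    hop_s: float = amp_mod.DEFAULT_HOP_S,
    schemes: Sequence[str] = ("valence_bin", "arousal_bin", "video_type"),
    zero_method: str = "wilcox",
) -> CohortResults:
    """Run the full pipeline and statistical surface on a cohort.

    ``cohort`` is either an object with ``iter_sessions()`` (see
    :class:`faceemg.synthetic_data.Cohort`) or an iterable of
    ``(recording, schedule, ratings)`` tuples. Raw recordings are denoised;
    already-denoised recordings are used as-is. Sessions are processed one at
    a time, so memory stays bounded by a single recording.
    """
    sessions = cohort.iter_sessions() if hasattr(cohort, "iter_sessions") else cohort
    per_video_frames: list[pd.DataFrame] = []
    all_ratings: list[RatingRecord] = []
    schedule_template: SessionSchedule | None = None
    n_subjects = 0
    for recording, schedule, ratings in sessions:
        n_subjects += 1
        if schedule_template is None:
            schedule_template = schedule
        all_ratings.extend(ratings)
        if recording.stage == "raw":
            recording = prep_mod.denoise(recording)
        envs = amp_mod.normalized_envelopes(
            recording, method=method, window_s=window_s, hop_s=hop_s
        )
        for env in envs.values():
            per_video_frames.append(epochs_mod.per_video_amplitude(env, schedule))
    if schedule_template is None:
        raise ValueError("cohort contains no sessions")
    per_video = pd.concat(per_video_frames, ignore_index=True)

    means = {
        scheme: epochs_mod.condition_means(
            per_video, all_ratings, schedule_template, scheme
        )
        for scheme in set(schemes) | {"valence_level"}
    }
    paired = {
        scheme: paired_amplitude_analysis(means[scheme], scheme, zero_method)
        for scheme in schemes
    }
    manipulation = manipulation_check(all_ratings, schedule_template)

    level_means = means["valence_level"]
    corr_rows = []
    trend_rows = []
    for channel in MODALITIES:
        sub = level_means[level_means["channel"] == channel]
        levels = sub["condition"].astype(int).to_numpy()
        values = sub["value"].to_numpy()
        for lo, hi in SEGMENTS:
            try:
                res = segment_pearson(levels, values, lo, hi)
                corr_rows.append(
                    {"channel": channel, "seg_lo": lo, "seg_hi": hi,
                     "r": res.r, "p": res.p, "n": res.n}
                )
            except (ValueError, DegenerateComparisonError):
                corr_rows.append(
                    {"channel": channel, "seg_lo": lo, "seg_hi": hi,
                     "r": np.nan, "p": np.nan, "n": 0}
                )
        fit = quadratic_trend(levels, values)
        trend_rows.append(
            {
                "channel": channel,
                "quadratic": fit.quadratic,
                "linear": fit.linear,
                "intercept": fit.intercept,
                "se_quadratic": fit.se[0],
                "ci95_quadratic": fit.ci95_halfwidth[0],
                "n": fit.n,
            }
        )
    return CohortResults(
        per_video=per_video,
        condition_means=means,
        paired=paired,
        manipulation=manipulation,
        correlations=pd.DataFrame(corr_rows),
        trends=pd.DataFrame(trend_rows),
        n_subjects=n_subjects,
    )


def write_results(results: CohortResults, out_dir: str | Path) -> Path:
    """Write the tidy CSV tables and the text report of a cohort analysis."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.concat(results.condition_means.values(), ignore_index=True).to_csv(
        out_dir / "condition_means.csv", index=False
    )
    paired = pd.concat(
        [t.assign(scheme=s) for s, t in results.paired.items()],
        ignore_index=True,
    )
    paired.to_csv(out_dir / "paired_tests.csv", index=False)
    results.manipulation.table.to_csv(
        out_dir / "manipulation_check.csv", index=False
    )
    results.correlations.to_csv(out_dir / "correlations.csv", index=False)
    results.trends.to_csv(out_dir / "trends.csv", index=False)
    (out_dir / "report.txt").write_text(results.summary())
    return out_dir
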