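"""Non-inferiority statistics for paired agreement values.

The study design this module serves is asymmetric: one reference rater
anchors the comparison, a second rater provides the *inter-expert*
agreement, and a model provides the *model-expert* agreement on the same
cases.  For each metric we test, per case pair, whether the model-expert
agreement is no worse than the inter-expert agreement by more than a
non-inferiority margin delta:

* metrics on [0, 1]: delta = 0.2 (20 % of the metric range);
* AVD: delta = 3 ml; HD95: delta = 3 mm.

The per-case difference is oriented so that positive values support
non-inferiority (for higher-is-better metrics ``model - inter + delta``,
for lower-is-better metrics ``inter - model + delta``), and the one-sided
null "median difference <= 0" is tested with a paired t-test when a
Shapiro-Wilk test does not reject normality of the differences, and with
the one-sided Wilcoxon signed-rank test otherwise.  P-values are adjusted
across the battery with the Holm-Bonferroni step-down procedure, and the
medians of both agreement series are reported with percentile-bootstrap
confidence intervals.

Shifting the differences by the margin and testing the shifted median
against zero is equivalent, under the paired-shift model, to shifting one
series before ranking; it is used because signed-rank tests are not
shift-invariant in general and this form keeps the orientation explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError
from .masks import SegmentationCase
from .metrics import MetricSpec, default_battery, evaluate_pair

__all__ = [
    "Margins",
    "NonInferiorityConfig",
    "AgreementTable",
    "NonInferiorityResult",
    "MarginDerivation",
    "shapiro_normality_p",
    "wilcoxon_signed_rank_one_sided",
    "noninferiority_test",
    "holm_bonferroni",
    "bootstrap_median_ci",
    "spearman_rho",
    "derive_margins",
    "run_noninferiority_battery",
    "build_agreement_table",
    "battery_to_dataframe",
]

INTER = "inter_expert"
MODEL = "model_expert"


@dataclass(frozen=True)
class Margins:
    """Non-inferiority margins per metric family."""

    relative: float = 0.2  # metrics on [0, 1]
    avd_ml: float = 3.0
    hd95_mm: float = 3.0

    def __post_init__(self) -> None:
        if min(self.relative, self.avd_ml, self.hd95_mm) <= 0:
            raise ValueError("all margins must be positive")

    def margin_for(self, spec: MetricSpec) -> float:
        if spec.range == "unit_interval":
            return self.relative
        if spec.units == "ml":
            return self.avd_ml
        if spec.units == "mm":
            return self.hd95_mm
        raise ValueError(f"no margin rule for metric {spec.label}")


@dataclass
class NonInferiorityConfig:
    alpha: float = 0.05
    margins: Margins = field(default_factory=Margins)
    n_boot: int = 10_000
    ci_level: float = 0.95
    seed: int = 0
    normality_alpha: float = 0.05
    zero_handling: str = "discard"  # or "pratt"
    family_size: int | None = None  # override Holm family size (>= number of tests run)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.n_boot < 1000:
            raise ValueError(f"n_boot must be >= 1000, got {self.n_boot}")
        if not 0 < self.ci_level < 1:
            raise ValueError(f"ci_level must be in (0,1), got {self.ci_level}")
        if self.zero_handling not in ("discard", "pratt"):
            raise ValueError(f"zero_handling must be 'discard' or 'pratt', got {self.zero_handling!r}")


class AgreementTable:
    """Per-case, per-metric agreement values for the two pairings of a cohort.

    Backed by a DataFrame indexed by case_id with MultiIndex columns
    ``(pairing, metric)`` where pairing is ``inter_expert`` or
    ``model_expert``.  Undefined metric values are stored as NaN and removed
    pairwise-complete by the tests.
    """

    def __init__(self, data: pd.DataFrame, metadata: dict | None = None):
        if not isinstance(data.columns, pd.MultiIndex) or data.columns.nlevels != 2:
            raise ValueError("AgreementTable needs MultiIndex columns (pairing, metric)")
        self.data = data.sort_index()
        self.metadata = dict(metadata or {})

    @property
    def case_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def metrics(self) -> list[str]:
        return sorted({m for _, m in self.data.columns})

    def series(self, pairing: str, metric: str) -> pd.Series:
        return self.data[(pairing, metric)]

    def to_long(self) -> pd.DataFrame:
        long = self.data.stack(level=[0, 1], future_stack=True).rename("value").reset_index()
        long.columns = ["case_id", "pairing", "metric", "value"]
        return long.sort_values(["case_id", "pairing", "metric"]).reset_index(drop=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_long(cls, long: pd.DataFrame, metadata: dict | None = None) -> "AgreementTable":
        wide = long.pivot_table(
            index="case_id", columns=["pairing", "metric"], values="value", dropna=False
        )
        return cls(wide, metadata)

    @classmethod
    def from_csv(cls, path: str | Path, metadata: dict | None = None) -> "AgreementTable":
        return cls.from_long(pd.read_csv(path), metadata)


@dataclass
class NonInferiorityResult:
    metric: MetricSpec
    n_cases_used: int
    median_inter: float
    median_model: float
    ci_inter: tuple[float, float]
    ci_model: tuple[float, float]
    margin: float
    test_used: str  # "wilcoxon" | "paired_t" | "degenerate"
    shapiro_p: float
    p_raw: float | None
    p_adjusted: float | None = None
    non_inferior: bool | None = None
    notes: str = ""


def shapiro_normality_p(values: Sequence[float]) -> float:
    """Shapiro-Wilk p-value for the null of normality (test-selection gate only)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientDataError(f"Shapiro test needs n >= 3, got {x.size}")
    if x.size > 5000:
        raise InsufficientDataError(f"Shapiro test supports n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        warnings.warn("constant input: no normal fit exists, returning p = 0", stacklevel=2)
        return 0.0
    return float(sps.shapiro(x).pvalue)


def wilcoxon_signed_rank_one_sided(
    deltas: Sequence[float], alternative: str = "greater", zero_handling: str = "discard"
) -> float:
    """One-sided Wilcoxon signed-rank p-value for a shift above zero.

    Exact p by enumeration of the 2^n sign assignments when n <= 20 with no
    ties among the absolute values and no zeros; normal approximation with
    continuity and tie correction otherwise.  Zeros are discarded before
    ranking by default (Wilcoxon's method) or kept with Pratt's method.
    """
    if alternative != "greater":
        raise ValueError("only alternative='greater' is supported")
    d = np.asarray(deltas, dtype=float)
    nonzero = d[d != 0]
    if nonzero.size == 0:
        if d.size == 0:
            raise InsufficientDataError("empty delta vector")
        warnings.warn("all deltas are zero: p = 1 (no evidence either way)", stacklevel=2)
        return 1.0
    if zero_handling == "discard":
        d_use, zero_method = nonzero, "wilcox"
    elif zero_handling == "pratt":
        d_use, zero_method = d, "pratt"
    else:
        raise ValueError(f"unknown zero_handling {zero_handling!r}")
    if nonzero.size < 5:
        raise InsufficientDataError(
            f"signed-rank test needs >= 5 nonzero pairs, got {nonzero.size}"
        )
    has_ties = np.unique(np.abs(d_use)).size < d_use.size
    has_zeros = bool(np.any(d_use == 0))
    exact = d_use.size <= 20 and not has_ties and not has_zeros
    res = sps.wilcoxon(
        d_use,
        zero_method=zero_method,
        alternative="greater",
        method="exact" if exact else "approx",
        correction=not exact,
    )
    return float(res.pvalue)


def holm_bonferroni(p_raw: Sequence[float], family_size: int | None = None) -> list[float]:
    """Holm step-down adjusted p-values, returned in input order.

    ``family_size`` lets a caller correct for tests performed outside this
    call (it must be >= len(p_raw)); padding with p = 1 entries reproduces
    the larger family.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if family_size is None else int(family_size)
    if m < len(p):
        raise ValueError(f"family_size {m} smaller than number of p-values {len(p)}")
    padded = np.concatenate([p, np.ones(m - len(p))])
    if padded.size == 0:
        return []
    adjusted = multipletests(padded, method="holm")[1]
    return [float(v) for v in adjusted[: len(p)]]


def bootstrap_median_ci(
    values: Sequence[float], n_boot: int = 10_000, level: float = 0.95, seed: int = 0
) -> tuple[float, float, float]:
    """(median, lower, upper): percentile-bootstrap CI of the median."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"bootstrap CI needs n >= 2, got {x.size}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(int(n_boot), x.size))
    meds = np.median(x[idx], axis=1)
    alpha = 1.0 - level
    lower, upper = np.quantile(meds, [alpha / 2, 1 - alpha / 2])
    return float(np.median(x)), float(lower), float(upper)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties; NaN if degenerate."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must be paired")
    if xa.size < 3:
        raise InsufficientDataError(f"Spearman correlation needs n >= 3, got {xa.size}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        warnings.warn("constant input vector: Spearman correlation undefined", stacklevel=2)
        return float("nan")
    return float(sps.spearmanr(xa, ya).statistic)


def oriented_deltas(
    inter: np.ndarray, model: np.ndarray, spec: MetricSpec, margin: float
) -> np.ndarray:
    """Per-case differences oriented so that positive supports non-inferiority."""
    if spec.direction == "higher_better":
        return model - inter + margin
    return inter - model + margin


def noninferiority_test(
    inter: Sequence[float],
    model: Sequence[float],
    spec: MetricSpec,
    margin: float,
    cfg: NonInferiorityConfig,
    *,
    boot_seed: int | None = None,
) -> NonInferiorityResult:
    """Paired non-inferiority test of model-expert vs inter-expert agreement.

    Cases where either value is undefined (NaN) are dropped pairwise-
    complete.  The p_adjusted / non_inferior fields are left unset; the
    battery runner fills them after Holm correction.
    """
    inter_a = np.asarray(inter, dtype=float)
    model_a = np.asarray(model, dtype=float)
    if inter_a.shape != model_a.shape:
        raise ValueError("inter and model series must be paired")
    ok = ~(np.isnan(inter_a) | np.isnan(model_a))
    inter_a, model_a = inter_a[ok], model_a[ok]
    n = int(inter_a.size)
    if n < 5:
        raise InsufficientDataError(
            f"{spec.label}: non-inferiority test needs >= 5 complete pairs, got {n}"
        )
    deltas = oriented_deltas(inter_a, model_a, spec, margin)

    notes = ""
    if np.all(deltas == 0):
        test_used, shapiro_p, p_raw = "degenerate", 0.0, 1.0
        notes = "all oriented differences are zero"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shapiro_p = shapiro_normality_p(deltas)
        if shapiro_p >= cfg.normality_alpha:
            test_used = "paired_t"
            p_raw = float(sps.ttest_1samp(deltas, 0.0, alternative="greater").pvalue)
        else:
            test_used = "wilcoxon"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p_raw = wilcoxon_signed_rank_one_sided(deltas, zero_handling=cfg.zero_handling)

    seed = cfg.seed if boot_seed is None else boot_seed
    med_i, lo_i, hi_i = bootstrap_median_ci(inter_a, cfg.n_boot, cfg.ci_level, seed)
    med_m, lo_m, hi_m = bootstrap_median_ci(model_a, cfg.n_boot, cfg.ci_level, seed + 1)
    return NonInferiorityResult(
        metric=spec,
        n_cases_used=n,
        median_inter=med_i,
        median_model=med_m,
        ci_inter=(lo_i, hi_i),
        ci_model=(lo_m, hi_m),
        margin=margin,
        test_used=test_used,
        shapiro_p=shapiro_p,
        p_raw=p_raw,
        notes=notes,
    )


@dataclass
class MarginDerivation:
    """Margins derived from the observed inter-expert variability.

    ``unit_interval`` / ``si_units`` are the means, over the metrics of each
    family, of the mean absolute per-case difference between two
    inter-expert agreement series.  ``defaults`` carries the rounded
    operative margins actually applied by the battery.
    """

    unit_interval: float
    si_units: float
    n_cases: int
    defaults: Margins = field(default_factory=Margins)


def derive_margins(
    inter_tables: Sequence[AgreementTable], specs: Iterable[MetricSpec] | None = None
) -> MarginDerivation:
    """Derive family margins as the average difference in inter-expert agreements.

    Requires at least two agreement tables whose ``inter_expert`` pairing
    compares two different expert pairs against the same reference.
    """
    if len(inter_tables) < 2:
        raise InsufficientDataError("margin derivation needs >= 2 inter-expert pairings")
    if specs is None:
        specs = default_battery()
    t1, t2 = inter_tables[0], inter_tables[1]
    unit_diffs: list[float] = []
    si_diffs: list[float] = []
    n_cases = 0
    for spec in specs:
        s1 = t1.series(INTER, spec.label)
        s2 = t2.series(INTER, spec.label)
        joined = pd.concat([s1, s2], axis=1, join="inner").dropna()
        if joined.empty:
            raise InsufficientDataError(f"{spec.label}: no complete inter-expert pairs")
        n_cases = max(n_cases, len(joined))
        mean_abs = float(np.mean(np.abs(joined.iloc[:, 0].to_numpy() - joined.iloc[:, 1].to_numpy())))
        if spec.range == "unit_interval":
            unit_diffs.append(mean_abs)
        else:
            si_diffs.append(mean_abs)
    unit = float(np.mean(unit_diffs)) if unit_diffs else float("nan")
    si = float(np.mean(si_diffs)) if si_diffs else float("nan")
    if unit == 0 or si == 0:
        warnings.warn("derived margin is zero (identical inter-expert series)", stacklevel=2)
    return MarginDerivation(unit_interval=unit, si_units=si, n_cases=n_cases)


def run_noninferiority_battery(
    table: AgreementTable,
    cfg: NonInferiorityConfig,
    specs: Iterable[MetricSpec] | None = None,
) -> list[NonInferiorityResult]:
    """Run one non-inferiority test per metric and Holm-adjust across the run.

    Metrics with fewer than 5 complete pairs are reported with
    ``p_raw = None`` and are excluded from the Holm family; the family size
    can be enlarged via ``cfg.family_size`` to account for external tests.
    """
    if specs is None:
        specs = default_battery()
    specs = list(specs)
    seed_seq = np.random.SeedSequence(cfg.seed)
    boot_seeds = [int(c.generate_state(1)[0] % 2**31) for c in seed_seq.spawn(len(specs))]
    results: list[NonInferiorityResult] = []
    for spec, bseed in zip(specs, boot_seeds):
        margin = cfg.margins.margin_for(spec)
        inter = table.series(INTER, spec.label).to_numpy()
        model = table.series(MODEL, spec.label).to_numpy()
        try:
            res = noninferiority_test(inter, model, spec, margin, cfg, boot_seed=bseed)
        except InsufficientDataError as exc:
            n_ok = int(np.count_nonzero(~(np.isnan(inter) | np.isnan(model))))
            res = NonInferiorityResult(
                metric=spec,
                n_cases_used=n_ok,
                median_inter=float("nan"),
                median_model=float("nan"),
                ci_inter=(float("nan"), float("nan")),
                ci_model=(float("nan"), float("nan")),
                margin=margin,
                test_used="none",
                shapiro_p=float("nan"),
                p_raw=None,
                notes=str(exc),
            )
        results.append(res)
    tested = [r for r in results if r.p_raw is not None]
    adjusted = holm_bonferroni([r.p_raw for r in tested], family_size=cfg.family_size)
    for r, p_adj in zip(tested, adjusted):
        r.p_adjusted = p_adj
        r.non_inferior = bool(p_adj < cfg.alpha)
    return results


def build_agreement_table(
    cases: Sequence[SegmentationCase],
    reference: str,
    comparison: str,
    model: str,
    specs: Iterable[MetricSpec] | None = None,
) -> AgreementTable:
    """Evaluate a cohort into the two-pairing agreement table.

    Per case the inter-expert pairing compares the comparison expert against
    the reference expert (pred = comparison, ref = reference) and the
    model-expert pairing compares the model prediction against the same
    comparison expert (pred = model, ref = comparison), mirroring a design
    where the reference rater anchors training and the remaining raters and
    the model are evaluated against each other.
    """
    if specs is None:
        specs = default_battery()
    specs = list(specs)
    rows = {}
    for case in cases:
        inter_res = evaluate_pair(case[comparison], case[reference], specs, (comparison, reference))
        model_res = evaluate_pair(case[model], case[comparison], specs, (model, comparison))
        row = {}
        for res in inter_res:
            row[(INTER, res.spec.label)] = res.value
        for res in model_res:
            row[(MODEL, res.spec.label)] = res.value
        rows[case.case_id] = row
    data = pd.DataFrame.from_dict(rows, orient="index")
    data.columns = pd.MultiIndex.from_tuples(data.columns, names=["pairing", "metric"])
    meta = {"reference": reference, "comparison": comparison, "model": model}
    return AgreementTable(data, meta)


def battery_to_dataframe(results: Sequence[NonInferiorityResult]) -> pd.DataFrame:
    """Flatten battery results into a report table (one row per metric)."""
    rows = []
    for r in results:
        rows.append(
            {
                "metric": r.metric.label,
                "units": r.metric.units,
                "n_cases_used": r.n_cases_used,
                "median_inter": r.median_inter,
                "ci_inter_low": r.ci_inter[0],
                "ci_inter_high": r.ci_inter[1],
                "median_model": r.median_model,
                "ci_model_low": r.ci_model[0],
                "ci_model_high": r.ci_model[1],
                "margin": r.margin,
                "test_used": r.test_used,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "non_inferior": r.non_inferior,
                "notes": r.notes,
            }
        )
    return pd.DataFrame(rows)
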