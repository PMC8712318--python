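"""Mitochondrial genome-wide association scan for CD4 outcomes.

The scan regresses a CD4 outcome on each retained mtDNA substitution
(0/1 carrier coding) with sociodemographic and clinical covariates,
using least-absolute-deviation (median) regression with case-resampling
bootstrap inference — the model family chosen because CD4 outcomes
violate the homoscedastic-normal residual assumptions of ordinary least
squares (checked by :func:`residual_diagnostics`).

Two outcome models mirror the cohort design:

``cd4_pre``
    Pre-treatment CD4 count on gender, age, ethnicity and HIV
    transmission mode.
``cd4_change``
    Post-treatment CD4 count with the pre-treatment count as a
    covariate (a change-score model), additionally adjusting for ART
    regimen class and treatment duration.

Substitutions are prevalence-filtered to carrier frequencies strictly
between 1% and 99%; with 287 retained substitutions and both outcomes
the scan performs 574 tests and the Bonferroni threshold is
0.05/574 = 8.71e-5.

Inference per substitution: the coefficient is the LAD point estimate
on the full data; the standard error is the standard deviation of the
coefficient over B case-resampled replicate fits; CI = beta +/- 1.96 SE,
t = beta / SE and p = 2(1 - Phi(|t|)).  Each substitution gets an
independent seed stream derived from the master seed and the column
key, so results are invariant to column order.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calling import CohortCalls
from .lad import bootstrap_two_group, lad_fit, lad_fit_batch, two_group_shortcut
from .reference import MitoReference

STANDARD_COVARIATES: dict[str, tuple[str, ...]] = {
    "cd4_pre": ("gender", "age", "ethnicity", "transmission"),
    "cd4_change": (
        "gender", "age", "ethnicity", "transmission", "cd4_pre",
        "regimen", "duration",
    ),
}

_OUTCOME_COLUMN = {"cd4_pre": "cd4_pre", "cd4_change": "cd4_post"}


class ScanError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """One outcome model of the scan.

    ``covariates=None`` selects the standard set for the outcome.
    Covariates are encoded as fixed reference-level dummies: male,
    Han ethnicity, heterosexual transmission, the zidovudine-based
    regimen and duration < 3 months are the reference levels.
    """

    outcome: str = "cd4_change"
    covariates: tuple[str, ...] | None = None
    bootstrap: int = 1000
    seed: int = 0
    alpha: float = 0.05
    polish: str = "restricted"  # full-data fit polish mode (see lad_fit)

    def __post_init__(self) -> None:
        if self.outcome not in _OUTCOME_COLUMN:
            raise ScanError(f"unknown outcome {self.outcome!r}")
        if self.bootstrap < 1:
            raise ScanError("bootstrap replications must be >= 1")

    @property
    def covariate_names(self) -> tuple[str, ...]:
        if self.covariates is None:
            return STANDARD_COVARIATES[self.outcome]
        return self.covariates


# ---------------------------------------------------------------------------
# genotype matrix


def genotype_matrix(
    calls: CohortCalls, include_ambiguous: bool = True
) -> pd.DataFrame:
    """Participants x substitution-types 0/1 carrier matrix (no indels)."""
    types = calls.type_registry()
    types = types[types["kind"] == "substitution"]
    if not include_ambiguous:
        types = types[types["definite"]]
    keys = list(types["m_notation"])
    samples = calls.sample_ids
    mat = pd.DataFrame(0, index=samples, columns=keys, dtype=np.int8)
    for sid, variant_list in calls.per_sample.items():
        for v, _ in variant_list:
            if v.kind == "substitution" and v.m_notation in mat.columns:
                mat.loc[sid, v.m_notation] = 1
    mat.index.name = "id"
    return mat


@dataclass
class FilterResult:
    matrix: pd.DataFrame
    kept: list[str]
    dropped: list[str]
    low: float
    high: float

    @property
    def min_kept_count(self) -> int:
        return int(self.matrix.sum(axis=0).min())

    @property
    def max_kept_count(self) -> int:
        return int(self.matrix.sum(axis=0).max())


def prevalence_filter(
    matrix: pd.DataFrame, low: float = 0.01, high: float = 0.99
) -> FilterResult:
    """Keep substitutions with carrier prevalence strictly inside (low, high).

    With n = 724 and the 1%/99% bounds this retains carrier counts from
    8 through 716.
    """
    if matrix.empty:
        raise ScanError("empty genotype matrix")
    n = len(matrix)
    counts = matrix.sum(axis=0)
    keep = (counts / n > low) & (counts / n < high)
    kept = list(matrix.columns[keep])
    dropped = list(matrix.columns[~keep])
    return FilterResult(
        matrix=matrix[kept], kept=kept, dropped=dropped, low=low, high=high
    )


# ---------------------------------------------------------------------------
# design construction


def build_design(
    meta: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.Series, pd.DataFrame]:
    """Outcome vector and covariate design (with intercept), complete-case.

    Dummy codes: female=1, minority=1, transmission -> (homosexual,
    other) against heterosexual, regimen -> (d4T-based, others) against
    the zidovudine-based reference, duration >=3 months = 1.
    """
    needed = {"id", _OUTCOME_COLUMN[spec.outcome]}
    col_of = {
        "gender": "gender", "age": "age", "ethnicity": "ethnicity",
        "transmission": "transmission", "cd4_pre": "cd4_pre",
        "regimen": "regimen", "duration": "duration_class",
    }
    for cov in spec.covariate_names:
        if cov not in col_of:
            raise ScanError(f"unknown covariate {cov!r}")
        needed.add(col_of[cov])
    missing = needed - set(meta.columns)
    if missing:
        raise ScanError(f"metadata missing columns: {sorted(missing)}")

    frame = meta.set_index("id")
    cols: dict[str, pd.Series] = {"const": pd.Series(1.0, index=frame.index)}
    for cov in spec.covariate_names:
        if cov == "gender":
            cols["female"] = frame["gender"].eq("female").astype(float)
        elif cov == "age":
            cols["age"] = frame["age"].astype(float)
        elif cov == "ethnicity":
            cols["minority"] = frame["ethnicity"].ne("Han").astype(float)
        elif cov == "transmission":
            cols["trans_homosexual"] = frame["transmission"].eq(
                "homosexual"
            ).astype(float)
            cols["trans_other"] = frame["transmission"].eq("other").astype(float)
        elif cov == "cd4_pre":
            cols["cd4_pre"] = frame["cd4_pre"].astype(float)
        elif cov == "regimen":
            cols["regimen_d4t"] = frame["regimen"].eq(
                "EFV/NVP+3TC+d4T"
            ).astype(float)
            cols["regimen_other"] = frame["regimen"].eq("others").astype(float)
        elif cov == "duration":
            cols["duration_ge3"] = frame["duration_class"].eq(">=3").astype(float)
    X = pd.DataFrame(cols)
    y = frame[_OUTCOME_COLUMN[spec.outcome]].astype(float)
    ok = y.notna() & X.notna().all(axis=1)
    return y[ok], X[ok]


# ---------------------------------------------------------------------------
# diagnostics


def residual_diagnostics(y, X, alpha: float = 0.05) -> dict:
    """OLS residual checks motivating the median-regression family.

    Breusch-Pagan tests homoscedasticity and Shapiro-Wilk normality
    (subsampled above 5,000 residuals); ``ols_ok`` is True only when
    neither rejects at ``alpha``.  Degenerate (constant) outcomes return
    a flagged, error-free report.
    """
    import statsmodels.api as sm
    from statsmodels.stats.diagnostic import het_breuschpagan

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.ptp(y) == 0.0:
        return {
            "ols_ok": True, "degenerate": True,
            "bp_p": np.nan, "shapiro_p": np.nan,
        }
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    bp_stat, bp_p, _, _ = het_breuschpagan(resid, X)
    sample = resid if resid.size <= 5000 else resid[:: resid.size // 5000 + 1]
    sw_stat, sw_p = stats.shapiro(sample)
    return {
        "ols_ok": bool(bp_p > alpha and sw_p > alpha),
        "degenerate": False,
        "bp_stat": float(bp_stat),
        "bp_p": float(bp_p),
        "shapiro_stat": float(sw_stat),
        "shapiro_p": float(sw_p),
    }


# ---------------------------------------------------------------------------
# inference


@dataclass
class InferenceResult:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    t: float
    p: float
    n_dropped: int
    degenerate: bool = False


def _column_seed(master_seed: int, key: str) -> np.random.SeedSequence:
    return np.random.SeedSequence((int(master_seed), zlib.crc32(key.encode())))


def _degenerate_replicates(X3: np.ndarray) -> np.ndarray:
    """Replicates where any non-intercept column became constant."""
    if X3.shape[2] < 2:
        return np.zeros(X3.shape[0], dtype=bool)
    spans = X3[:, :, 1:].max(axis=1) - X3[:, :, 1:].min(axis=1)
    return (spans == 0.0).any(axis=1)


def bootstrap_inference(
    y: np.ndarray,
    X: np.ndarray,
    focus: int = 1,
    B: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    beta_full: np.ndarray | None = None,
    max_iter: int = 50,
) -> InferenceResult:
    """Case-resampling bootstrap for one median-regression coefficient.

    Resamples rows of (y, X) jointly B times, refits each replicate, and
    summarizes the ``focus`` coefficient: SE is the standard deviation
    of replicate estimates, CI = beta +/- 1.96 SE, t = beta/SE and
    p = 2(1 - Phi(|t|)).  Replicates whose resampled design is
    degenerate (a column gone constant) are dropped and counted; a
    zero-variance bootstrap distribution is flagged ``degenerate`` with
    an undefined p.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if beta_full is None:
        beta_full = lad_fit(y, X, polish="restricted")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    if p == 2 and focus == 1 and two_group_shortcut(y, X) is not None:
        # intercept + binary genotype: replicate fits are exact
        # group-median differences, vectorized over replicates
        ests, valid = bootstrap_two_group(y, X[:, 1], idx)
        focus_betas = ests[valid]
        n_dropped = int(B - valid.sum())
    else:
        X3 = X[idx]
        bad = _degenerate_replicates(X3)
        n_dropped = int(bad.sum())
        if n_dropped:
            X3 = X3[~bad]
            idx = idx[~bad]
        betas = lad_fit_batch(y[idx], X3, beta0=beta_full, max_iter=max_iter)
        focus_betas = betas[:, focus]
    if n_dropped > 0.1 * B:
        import warnings

        warnings.warn(
            f"{n_dropped}/{B} bootstrap replicates dropped as degenerate",
            stacklevel=2,
        )
    beta = float(beta_full[focus])
    se = float(np.std(focus_betas, ddof=1)) if len(focus_betas) > 1 else 0.0
    if se == 0.0:
        return InferenceResult(
            beta=beta, se=0.0, ci_low=beta, ci_high=beta,
            t=np.nan, p=np.nan, n_dropped=n_dropped, degenerate=True,
        )
    t = beta / se
    return InferenceResult(
        beta=beta,
        se=se,
        ci_low=beta - 1.96 * se,
        ci_high=beta + 1.96 * se,
        t=t,
        p=float(2.0 * stats.norm.sf(abs(t))),
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# the scan


@dataclass
class ScanResult:
    results: pd.DataFrame
    n_tests: int
    threshold: float
    alpha: float
    log: list[str] = field(default_factory=list)


def run_scan(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    specs: tuple[ModelSpec, ...] | ModelSpec,
    ref: MitoReference | None = None,
) -> ScanResult:
    """Fit every (substitution, outcome) model and apply Bonferroni.

    ``matrix`` is a prevalence-filtered 0/1 genotype matrix indexed by
    participant id.  The total test count is the sum over outcome models
    of the column count, and the genome-wide threshold is
    alpha / n_tests.  Results are sorted by p-value.  Deterministic
    given the model seeds; invariant to column and participant order up
    to each column's private seed stream.
    """
    if isinstance(specs, ModelSpec):
        specs = (specs,)
    if matrix.empty:
        raise ScanError("empty genotype matrix")
    alpha = specs[0].alpha
    n_tests = len(specs) * matrix.shape[1]
    threshold = alpha / n_tests
    log: list[str] = [f"{n_tests} tests; Bonferroni threshold {threshold:.3g}"]
    rows = []
    for spec in specs:
        y, Xbase = build_design(meta, spec)
        common = matrix.index.intersection(y.index)
        if len(common) <= Xbase.shape[1] + 1:
            raise ScanError(
                f"{spec.outcome}: only {len(common)} complete-case rows"
            )
        yv = y.loc[common].to_numpy()
        Xb = Xbase.loc[common]
        log.append(
            f"{spec.outcome}: n={len(common)}, B={spec.bootstrap}, "
            f"covariates={list(Xb.columns[1:])}"
        )
        for key in matrix.columns:
            g = matrix.loc[common, key].to_numpy(dtype=float)
            X = np.column_stack([Xb.iloc[:, 0].to_numpy(), g,
                                 Xb.iloc[:, 1:].to_numpy()])
            names = ["const", key] + list(Xb.columns[1:])
            beta_full = lad_fit(y=yv, X=X, polish=spec.polish,
                                column_names=names)
            inf = bootstrap_inference(
                yv, X, focus=1, B=spec.bootstrap,
                seed=_column_seed(spec.seed, f"{spec.outcome}:{key}"),
                beta_full=beta_full,
            )
            rows.append(
                {
                    "outcome": spec.outcome,
                    "substitution": key,
                    "region": _region_label(key, ref),
                    "carrier_count": int(matrix.loc[common, key].sum()),
                    "beta": inf.beta,
                    "se": inf.se,
                    "ci_low": inf.ci_low,
                    "ci_high": inf.ci_high,
                    "t": inf.t,
                    "p": inf.p,
                    "n_dropped_replicates": inf.n_dropped,
                }
            )
    results = pd.DataFrame(rows)
    results["significant_bonferroni"] = results["p"] < threshold
    results = results.sort_values("p", na_position="last").reset_index(drop=True)
    return ScanResult(
        results=results, n_tests=n_tests, threshold=threshold,
        alpha=alpha, log=log,
    )


def _region_label(key: str, ref: MitoReference | None) -> str | None:
    if ref is None:
        return None
    m = re.match(r"m\.(\d+)", key)
    if not m:
        return None
    regions = ref.region_of(int(m.group(1)))
    if not regions:
        return "non-coding"
    return "/".join(gene for gene, _ in regions)
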