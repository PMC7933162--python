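"""Sentence-type contrasts in 100-ms windows and the mixed-model check.

Eleven 100-ms windows tied to phrase onsets and offsets are compared
between sentence types with a studentized (bootstrap-t) test over
electrodes, FDR-corrected across windows x ROIs.  The contrast is then
re-examined in a linear mixed model on electrode-level window means with
a patient random intercept and patient covariates (age, epilepsy onset
age, sex, antiepileptic drug count, full-scale IQ, congenital lesion) as
fixed effects.  A power helper reports the smallest standardized effect a
one-sample two-sided t test can detect at a given n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.power import TTestPower
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from hgmod.cohort import PatientProfile, _as_rng
from hgmod.epoching import HighGammaTrace, align
from hgmod.pointwise import fdr_adjust


@dataclass(frozen=True)
class WindowDef:
    label: str
    anchor: str
    start_ms: float   # relative to anchor; window is [start, start+100)
    end_ms: float

    def __post_init__(self) -> None:
        if not np.isclose(self.end_ms - self.start_ms, 100.0):
            raise ValueError("windows must span exactly 100 ms")


def default_windows() -> list[WindowDef]:
    """The default eleven windows.

    For each phrase N: Na = [-100, 0) before N onset, Nb = [0, 100) after
    N onset, Nc = [-100, 0) before N offset, Nd = [0, 100) after N offset;
    window 1a is omitted because it falls in the pre-stimulus period.
    """
    out: list[WindowDef] = []
    for n in (1, 2, 3):
        for tag, anchor, start in (
            ("a", f"p{n}_onset", -100.0),
            ("b", f"p{n}_onset", 0.0),
            ("c", f"p{n}_offset", -100.0),
            ("d", f"p{n}_offset", 0.0),
        ):
            if n == 1 and tag == "a":
                continue
            out.append(WindowDef(f"{n}{tag}", anchor, start, start + 100.0))
    return out


@dataclass
class WindowContrast:
    roi: str
    hemisphere: str
    window: str
    mean_diff: float          # percent, groupA - groupB
    t_stat: float
    ci95: tuple[float, float]
    p_raw: float
    p_fdr: float = np.nan
    n_a: int = 0
    n_b: int = 0


@dataclass
class LMMResult:
    roi: str
    hemisphere: str
    window: str
    coefficients: pd.DataFrame   # index: term; columns: estimate, se, ci_low, ci_high, p
    random_intercept_var: float
    p_fdr: float = np.nan        # sentence-type term, after FDR
    converged: bool = True
    singular: bool = False

    @property
    def sentence_type_effect(self) -> pd.Series:
        return self.coefficients.loc["sentence_type"]


def extract_window_values(
    trace: HighGammaTrace,
    window: WindowDef,
    *,
    sentence_type: str | None = None,
) -> np.ndarray:
    """Per-electrode mean percent change inside one 100-ms window.

    Each electrode's trial-averaged anchored trace is averaged over the
    window's ten 10-ms bins (half-open [start, end)).  Raises if any
    retained trial lacks coverage of the window.
    """
    anchored = align(trace, window.anchor, (window.start_ms, window.end_ms))
    step = anchored.time_step
    inside = (anchored.times >= window.start_ms) & (anchored.times < window.end_ms)
    data = anchored.data[:, :, inside]
    if sentence_type is not None:
        tmask = anchored.sentence_types == sentence_type
        data = data[tmask]
        ids = [t for t, m in zip(anchored.trial_ids, tmask) if m]
    else:
        ids = list(anchored.trial_ids)
    missing = [ids[k] for k in range(data.shape[0])
               if np.isnan(data[k]).any()]
    if missing:
        raise ValueError(
            f"window {window.label} not covered by trials: {missing[:5]}"
            + ("..." if len(missing) > 5 else ""))
    return data.mean(axis=(0, 2))


def studentized_bootstrap_contrast(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_boot: int = 2000,
    rng_seed=None,
    *,
    ci: float = 0.95,
) -> dict:
    """Bootstrap-t two-sample test for a difference in group means.

    Electrodes are resampled with replacement within each group; the pivot
    is t = (d - d_hat) / se(d), with the unpooled (Welch) standard error.
    Returns mean_diff, t_stat, two-sided p (add-one convention) and a
    percentile-t CI.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 electrodes")
    rng = _as_rng(rng_seed)

    def _se(x: np.ndarray, y: np.ndarray, axis=None) -> np.ndarray:
        return np.sqrt(x.var(ddof=1, axis=axis) / x.shape[-1]
                       + y.var(ddof=1, axis=axis) / y.shape[-1])

    d = a.mean() - b.mean()
    se = _se(a, b)
    if se == 0:
        t0 = 0.0 if d == 0 else np.inf
    else:
        t0 = d / se

    ia = rng.integers(0, a.size, size=(n_boot, a.size))
    ib = rng.integers(0, b.size, size=(n_boot, b.size))
    ra, rb = a[ia], b[ib]
    d_star = ra.mean(axis=1) - rb.mean(axis=1)
    se_star = _se(ra, rb, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_star = (d_star - d) / se_star
    t_star = t_star[np.isfinite(t_star)]
    if t_star.size == 0:
        p = 1.0
        lo = hi = d
    else:
        p = (1.0 + np.sum(np.abs(t_star) >= abs(t0))) / (t_star.size + 1.0)
        qlo, qhi = np.percentile(t_star, [100 * (1 - ci) / 2, 100 * (1 + ci) / 2])
        lo, hi = d - qhi * se, d - qlo * se
    return {"mean_diff": float(d), "t_stat": float(t0), "p": float(p),
            "ci": (float(lo), float(hi)), "n_a": a.size, "n_b": b.size}


def contrast_windows(
    traces_by_roi: dict[tuple[str, str], HighGammaTrace] | None = None,
    *,
    values: dict[tuple[str, str, str], tuple[np.ndarray, np.ndarray]] | None = None,
    windows: list[WindowDef] | None = None,
    n_boot: int = 2000,
    rng_seed=None,
) -> list[WindowContrast]:
    """Studentized-bootstrap contrasts for every ROI x window, with BH-FDR
    across the whole family.

    ``values`` maps (roi, hemisphere, window_label) to the two per-electrode
    value vectors (concrete_first, wh_first); it can be supplied directly
    or computed upstream with :func:`extract_window_values`.
    """
    if values is None:
        raise ValueError("supply precomputed window values")
    rng = _as_rng(rng_seed)
    out: list[WindowContrast] = []
    for (roi, hemi, label), (va, vb) in values.items():
        r = studentized_bootstrap_contrast(va, vb, n_boot, rng)
        out.append(WindowContrast(
            roi=roi, hemisphere=hemi, window=label,
            mean_diff=r["mean_diff"], t_stat=r["t_stat"], ci95=r["ci"],
            p_raw=r["p"], n_a=r["n_a"], n_b=r["n_b"]))
    if out:
        adj = fdr_adjust(np.array([c.p_raw for c in out]))
        for c, q in zip(out, adj):
            c.p_fdr = float(q)
    return out


_COVARIATE_TERMS = ("age", "epilepsy_onset_age", "sex", "n_antiepileptic_drugs",
                    "fiq", "congenital_lesion")


def fit_window_lmm(
    data: pd.DataFrame,
    patients: list[PatientProfile] | None = None,
    *,
    roi: str = "",
    hemisphere: str = "",
    window: str = "",
    df_method: str = "patients",
) -> LMMResult:
    """Linear mixed model on electrode-level window values.

    ``data`` needs columns ``value`` (percent change), ``sentence_type``,
    ``patient_id``; patient covariates are merged in from ``patients`` (or
    may already be present as columns).  The model is

        value ~ sentence_type + age + epilepsy_onset_age + sex
                + n_antiepileptic_drugs + fiq + congenital_lesion
                + (1 | patient)

    fit by REML.  Inference on each coefficient is a Wald t test with
    patient-count-based degrees of freedom (n_patients - n_fixed_terms).
    """
    df = data.copy()
    if patients is not None:
        cov = pd.DataFrame([{
            "patient_id": p.patient_id,
            "age": p.age,
            "epilepsy_onset_age": p.epilepsy_onset_age,
            "sex": 1.0 if p.sex == "female" else 0.0,
            "n_antiepileptic_drugs": float(p.n_antiepileptic_drugs),
            "fiq": p.fiq,
            "congenital_lesion": 1.0 if p.congenital_lesion else 0.0,
        } for p in patients])
        df = df.merge(cov, on="patient_id", how="left", suffixes=("", "_cov"))
    n_patients = df["patient_id"].nunique()
    if n_patients < 2:
        raise ValueError("mixed model needs at least 2 patients")

    y = df["value"].to_numpy(dtype=float)
    X = pd.DataFrame({"Intercept": 1.0,
                      "sentence_type": (df["sentence_type"] == "concrete_first").astype(float)})
    for term in _COVARIATE_TERMS:
        if term in df.columns and df[term].nunique() > 1:
            X[term] = df[term].astype(float)
    if np.isnan(X.to_numpy()).any():
        raise ValueError("covariates incomplete for some patients")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(
            "fixed-effect design is rank deficient (patient-level covariates "
            "need more patients than terms); drop covariates or add patients")

    singular = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = MixedLM(y, X.to_numpy(), groups=df["patient_id"].to_numpy())
        try:
            fit = model.fit(reml=True, method="lbfgs")
        except Exception:
            fit = model.fit(reml=True, method="powell")
        converged = bool(getattr(fit, "converged", True))
        re_var = float(np.atleast_2d(fit.cov_re)[0, 0])
        if re_var < 1e-10:
            singular = True

    n_fixed = X.shape[1]
    ddf = max(n_patients - n_fixed, 1) if df_method == "patients" else max(len(df) - n_fixed, 1)
    est = fit.fe_params
    se = fit.bse_fe
    tvals = est / se
    pvals = 2 * stats.t.sf(np.abs(tvals), ddf)
    tcrit = stats.t.ppf(0.975, ddf)
    coef = pd.DataFrame({
        "estimate": est,
        "se": se,
        "ci_low": est - tcrit * se,
        "ci_high": est + tcrit * se,
        "t": tvals,
        "p": pvals,
    }, index=list(X.columns))
    return LMMResult(
        roi=roi, hemisphere=hemisphere, window=window,
        coefficients=coef,
        random_intercept_var=re_var,
        converged=converged,
        singular=singular,
    )


def lmm_windows(datasets: dict[tuple[str, str, str], pd.DataFrame],
                patients: list[PatientProfile] | None = None) -> list[LMMResult]:
    """Fit the mixed model per ROI x window and FDR-correct the
    sentence-type p-values across the family."""
    out = []
    for (roi, hemi, label), df in datasets.items():
        out.append(fit_window_lmm(df, patients, roi=roi, hemisphere=hemi,
                                  window=label))
    if out:
        adj = fdr_adjust(np.array([r.coefficients.loc["sentence_type", "p"]
                                   for r in out]))
        for r, q in zip(out, adj):
            r.p_fdr = float(q)
    return out


def detectable_effect_size(n: int, alpha: float = 0.05,
                           power: float = 0.8) -> float:
    """Smallest standardized one-sample mean difference detectable with a
    two-sided t test at sample size n (noncentral-t power solution)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    es = TTestPower().solve_power(effect_size=None, nobs=n, alpha=alpha,
                                  power=power, alternative="two-sided")
    return float(es)
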