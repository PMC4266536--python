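"""Predictive validity and specificity of arousal estimation methods.

A method's predictive validity is how much evidence its estimates give
for a known categorical arousal difference between two conditions.  The
condition contrast is fit as a general linear model with subject
effects (equivalent to a paired t-test); its residual sum of squares is
converted to a negative log likelihood

    LL = n · log(RSS / n)

(n observations; natural log), and methods are compared by the log
Bayes factor LBF = LL_method − LL_reference, with |LBF| > 3 ≈
ln(0.95/0.05) conventionally decisive.  Model complexity is identical
across methods and is ignored.  Lower LL (lower LBF) means higher
predictive validity; for a fixed contrast and n, LL is a strictly
decreasing function of the paired |t|.

Specificity is calibrated by randomly splitting each subject's trials
from a single condition into two pseudo-conditions, averaging each
half, and paired-testing across subjects; over many repetitions an
unbiased method is significant at the nominal alpha rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .glm import build_design, cofilter, fit_glm, glm_pipeline, reconstruct_amplitude
from .decomposition import aggregate, decomposition_trial_tables
from .io import EventTable
from .kernel import CANONICAL_LATENCY, make_kernel
from .peaks import peak_trial_table
from .preprocessing import (
    DEFAULT_HIGHPASS_HZ,
    DEFAULT_TARGET_FS,
    butter1_filter,
    preprocess,
    zscore,
)

__all__ = [
    "ValidityResult",
    "paired_contrast_fit",
    "neg_log_likelihood",
    "log_bayes_factor",
    "lbf_decision_threshold",
    "is_decisive",
    "specificity_test",
    "glm_specificity_test",
    "estimate_dataset",
    "compare_methods",
]

#: Conventional decisive log-Bayes-factor difference; ln(0.95/0.05) ≈ 3.
DECISIVE_LBF = 3.0
#: RSS floor used when a pathological (noiseless) fit yields RSS = 0.
RSS_EPS = 1e-12

METHODS = ("glm", "cda1", "cda2", "dda1", "dda2", "peak")


@dataclass
class ValidityResult:
    """Predictive-validity summary for one method on one contrast."""

    method: str
    contrast: tuple
    n: int
    rss: float
    ll: float
    lbf: float
    t: float
    df: int
    p: float
    decisive: bool = False
    degenerate: bool = False


def paired_contrast_fit(estimates: pd.DataFrame, contrast: tuple) -> dict:
    """Regress the condition contrast on the SA estimates, with subject effects.

    The contrast of interest is the response variable (coded +1 for the
    first contrast condition, −1 for the second) and the SA estimate is
    the predictor, alongside subject effects — equivalent to a paired
    t-test, and the resulting RSS is invariant to the scale of the
    estimates, so negative log likelihoods are comparable across
    methods.  `estimates` must hold exactly one value per (subject,
    condition) for the two contrast conditions and at least 3 subjects.
    Returns RSS (n = 2·S observations), the paired t statistic of the
    per-subject differences (first minus second condition), df = S − 1,
    and the two-sided p.  Constant nonzero differences make the contrast
    perfectly predictable (RSS 0, infinite t) and are flagged
    degenerate.
    """
    cond_a, cond_b = contrast
    df = estimates[estimates["condition"].isin([cond_a, cond_b])]
    wide = df.pivot_table(index="subject_id", columns="condition", values="value")
    if cond_a not in wide.columns or cond_b not in wide.columns or wide.isna().any().any():
        raise ValueError(f"every subject needs one value for both {contrast}")
    S = len(wide)
    if S < 3:
        raise ValueError(f"paired contrast needs >= 3 subjects, got {S}")
    long = wide.reset_index().melt(
        id_vars="subject_id", value_vars=[cond_a, cond_b],
        var_name="condition", value_name="value",
    )
    long["code"] = np.where(long["condition"] == cond_a, 1.0, -1.0)
    fit = smf.ols("code ~ C(subject_id) + value", data=long).fit()
    rss = float(fit.ssr)
    d = (wide[cond_a] - wide[cond_b]).to_numpy(dtype=float)
    sd = d.std(ddof=1)
    degenerate = False
    if sd == 0:
        if np.allclose(d, 0):
            t = 0.0
            p = 1.0
        else:
            t = np.inf if d.mean() > 0 else -np.inf
            p = 0.0
            degenerate = True
    else:
        t = float(d.mean() / (sd / np.sqrt(S)))
        p = float(2 * stats.t.sf(abs(t), S - 1))
    return {
        "rss": rss,
        "n": 2 * S,
        "t": t,
        "df": S - 1,
        "p": p,
        "degenerate": degenerate,
    }


def neg_log_likelihood(rss: float, n: int) -> float:
    """LL = n·log(RSS/n); lower LL means higher predictive validity.

    RSS = 0 (noiseless pathological fits) is floored at RSS_EPS so that
    comparisons stay finite; negative RSS is impossible and raises.
    """
    if rss < 0:
        raise ValueError(f"RSS must be non-negative, got {rss}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if rss == 0:
        warnings.warn("RSS = 0; flooring at eps for a finite LL")
        rss = RSS_EPS
    return float(n * np.log(rss / n))


def log_bayes_factor(
    ll_method: float, ll_reference: float,
    n_method: int | None = None, n_reference: int | None = None,
) -> float:
    """LBF = LL_method − LL_reference (same contrast, same n)."""
    if n_method is not None and n_reference is not None and n_method != n_reference:
        raise ValueError(
            f"LBF requires equal observation counts, got {n_method} vs {n_reference}"
        )
    return float(ll_method - ll_reference)


def lbf_decision_threshold(alpha: float = 0.05) -> float:
    """ln((1−alpha)/alpha): the LBF magnitude matching a classical p = alpha.

    At alpha = 0.05 this is ln(19) ≈ 2.94, conventionally rounded to 3.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(np.log((1 - alpha) / alpha))


def is_decisive(lbf: float, threshold: float = DECISIVE_LBF) -> bool:
    return abs(lbf) > threshold


def _as_trial_map(trial_values) -> dict:
    if isinstance(trial_values, pd.DataFrame):
        return {
            s: g["value"].to_numpy(dtype=float)
            for s, g in trial_values.groupby("subject_id")
        }
    return {s: np.asarray(v, dtype=float) for s, v in dict(trial_values).items()}


def _paired_p(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        return 1.0 if np.allclose(d, 0) else 0.0
    t = d.mean() / (sd / np.sqrt(len(d)))
    return float(2 * stats.t.sf(abs(t), len(d) - 1))


def specificity_test(
    trial_values,
    n_reps: int = 1000,
    alpha: float = 0.05,
    rng=None,
) -> int:
    """Split-half false-positive count over random same-condition splits.

    `trial_values`: per-subject per-trial SA estimates from ONE condition
    (a mapping subject → array, or an estimate-table DataFrame).  Per
    repetition, each subject's trials are randomly split into two equal
    halves (a random odd trial is discarded), each half is averaged, and
    the two pseudo-condition means are paired-tested across subjects.
    Returns the number of repetitions significant at `alpha`; an
    unbiased method yields ≈ alpha · n_reps.
    """
    rng = np.random.default_rng(rng)
    per_subject = _as_trial_map(trial_values)
    subjects = sorted(per_subject)
    for s in subjects:
        if len(per_subject[s]) < 2:
            raise ValueError(f"subject {s!r} has fewer than 2 trials")
    count = 0
    S = len(subjects)
    for _ in range(n_reps):
        a = np.empty(S)
        b = np.empty(S)
        for j, s in enumerate(subjects):
            v = per_subject[s][rng.permutation(len(per_subject[s]))]
            if len(v) % 2:
                v = v[:-1]  # permuted, so a random trial is discarded
            half = len(v) // 2
            a[j] = v[:half].mean()
            b[j] = v[half:].mean()
        if _paired_p(a, b) < alpha:
            count += 1
    return count


def glm_specificity_test(
    dataset,
    n_reps: int = 1000,
    alpha: float = 0.05,
    rng=None,
    highpass_hz: float = DEFAULT_HIGHPASS_HZ,
    target_fs: float = DEFAULT_TARGET_FS,
    kernel=None,
) -> int:
    """Split-half specificity for the convolution GLM.

    The GLM has no per-trial estimates, so each repetition relabels each
    subject's events into two random equal pseudo-conditions, refits the
    whole GLM, and paired-tests the reconstructed amplitudes across
    subjects.  `dataset` is a sequence of (recording, events) pairs from
    a single condition.
    """
    rng = np.random.default_rng(rng)
    pairs = _as_pairs(dataset)
    prepared = []
    for rec, events in pairs:
        if rec.fs == target_fs:
            values, fs = rec.values.astype(float), rec.fs
        else:
            values, fs = preprocess(rec.values, rec.fs, target_fs=target_fs), target_fs
        if kernel is None:
            kernel = make_kernel(fs, latency_shift=CANONICAL_LATENCY)
        y = zscore(butter1_filter(values, fs, highpass_hz, "highpass"))
        prepared.append((y, events.onsets, fs))
    S = len(prepared)
    count = 0
    for _ in range(n_reps):
        a = np.empty(S)
        b = np.empty(S)
        for j, (y, onsets, fs) in enumerate(prepared):
            k = len(onsets)
            perm = rng.permutation(k)
            if k % 2:
                perm = perm[:-1]
            half = len(perm) // 2
            labels = np.empty(k, dtype=object)
            labels[:] = "drop"
            labels[perm[:half]] = "A"
            labels[perm[half:]] = "B"
            keep = labels != "drop"
            ev = EventTable(onsets[keep], labels[keep])
            design = build_design(ev, len(y), fs, kernel)
            _, fdesign = cofilter(
                np.zeros(len(y)), design, highpass_hz
            )
            beta = fit_glm(y, fdesign)
            amps = {}
            for cond in ("A", "B"):
                b1 = beta[fdesign.labels.index((cond, "canonical"))]
                b2 = beta[fdesign.labels.index((cond, "derivative"))]
                amps[cond] = reconstruct_amplitude(b1, b2, kernel)
            a[j], b[j] = amps["A"], amps["B"]
        if _paired_p(a, b) < alpha:
            count += 1
    return count


def _as_pairs(dataset):
    """Normalise a dataset to a list of (recording, events) pairs."""
    from .simulate import ExperimentData, SubjectData

    if isinstance(dataset, ExperimentData):
        dataset = dataset.subjects
    pairs = []
    for item in dataset:
        if isinstance(item, SubjectData):
            pairs.append((item.recording, item.events))
        else:
            rec, events = item
            pairs.append((rec, events))
    return pairs


def estimate_dataset(
    dataset, method: str, variant: str = "raw", **kwargs
) -> pd.DataFrame:
    """Per-condition SA estimates for one method over a whole dataset."""
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    pairs = _as_pairs(dataset)
    tables = []
    for rec, events in pairs:
        if method == "glm":
            tables.append(glm_pipeline(rec, events, **kwargs))
        elif method in ("cda1", "cda2", "dda1", "dda2"):
            family = method[:3]
            t = decomposition_trial_tables(
                rec, events, families=(family,), variant=variant, **kwargs
            )[family]
            agg = aggregate(t, variant=variant, conditions=events.condition_labels)
            tables.append(agg[agg["method"] == method.upper()])
        else:
            t = peak_trial_table(rec, events, variant=variant, **kwargs)
            tables.append(
                aggregate(t, variant=variant, conditions=events.condition_labels)
            )
    return pd.concat(tables, ignore_index=True)


def compare_methods(
    dataset,
    methods=METHODS,
    contrast: tuple = ("aversive", "neutral"),
    reference: str = "glm",
    variant: str = "raw",
    **kwargs,
) -> pd.DataFrame:
    """Run every method on `dataset` and tabulate LL / LBF / paired t.

    Decomposition trial tables are computed once per family and shared
    between the two indices of that family.  The reference method's LBF
    is 0 by construction.  Within a comparison (fixed contrast and n)
    the ranking of methods by LL equals the reverse ranking by |t|; this
    is recomputed on every run and exposed via the returned columns.
    """
    methods = [m.lower() for m in methods]
    if reference not in methods:
        raise ValueError(f"reference {reference!r} must be among methods {methods}")
    pairs = _as_pairs(dataset)
    cache: dict = {}

    decomp_families = tuple(
        f for f in ("cda", "dda") if any(m.startswith(f) for m in methods)
    )

    def estimates_for(method: str) -> pd.DataFrame:
        family = {"cda1": "cda", "cda2": "cda", "dda1": "dda", "dda2": "dda"}.get(
            method, method
        )
        if family not in cache:
            if family == "glm":
                cache[family] = pd.concat(
                    [glm_pipeline(r, e, **kwargs) for r, e in pairs],
                    ignore_index=True,
                )
            elif family in ("cda", "dda"):
                # one shared deconvolution per recording for both families
                per_subject = [
                    decomposition_trial_tables(
                        r, e, families=decomp_families, variant=variant, **kwargs
                    )
                    for r, e in pairs
                ]
                for fam in decomp_families:
                    trial = pd.concat(
                        [d[fam] for d in per_subject], ignore_index=True
                    )
                    cache[fam] = aggregate(trial, variant=variant)
            else:
                trial = pd.concat(
                    [peak_trial_table(r, e, variant=variant, **kwargs) for r, e in pairs],
                    ignore_index=True,
                )
                cache[family] = aggregate(trial, variant=variant)
        est = cache[family]
        if method in ("cda1", "cda2", "dda1", "dda2"):
            est = est[est["method"] == method.upper()]
        return est

    results = {}
    for m in methods:
        fit = paired_contrast_fit(estimates_for(m), contrast)
        ll = neg_log_likelihood(fit["rss"], fit["n"])
        results[m] = ValidityResult(
            method=m,
            contrast=tuple(contrast),
            n=fit["n"],
            rss=fit["rss"],
            ll=ll,
            lbf=np.nan,
            t=fit["t"],
            df=fit["df"],
            p=fit["p"],
            degenerate=fit["degenerate"],
        )
    ll_ref = results[reference].ll
    n_ref = results[reference].n
    for m, r in results.items():
        r.lbf = log_bayes_factor(r.ll, ll_ref, r.n, n_ref)
        r.decisive = is_decisive(r.lbf)
    return pd.DataFrame(
        [
            {
                "method": r.method,
                "condition_a": r.contrast[0],
                "condition_b": r.contrast[1],
                "n": r.n,
                "rss": r.rss,
                "ll": r.ll,
                "lbf": r.lbf,
                "t": r.t,
                "df": r.df,
                "p": r.p,
                "decisive": r.decisive,
                "degenerate": r.degenerate,
            }
            for r in results.values()
        ]
    )
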