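"""Receptor-block quantification and insect LC50 estimation.

Two assays close the loop from behavioral hit to insecticidal mechanism:

* Two-electrode voltage clamp of oocytes expressing an insect GABA-gated
  chloride channel.  GABA evokes an inward current at -60 mV; a test
  compound co-applied with GABA reduces it.  Because the GABA response
  desensitizes slowly ("rundown"), the fractional loss measured on untreated
  control oocytes is divided out before the percent block is computed:
  ``remaining = I_coapp / I_pre``, ``block% = 100 x (1 - remaining/(1 - rundown))``,
  clipped to [0, 100].

* A corn-rootworm diet assay: wells of artificial diet carry a compound dose
  and 3-5 neonate larvae; after incubation a well is scored dead only if its
  least-affected larva is dead.  The median lethal dose is the 50% point of
  a two-parameter log-logistic model fitted to the binary well outcomes by
  maximum likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

EPOCH_LABELS = ("baseline", "gaba_only_pre", "coapplication", "gaba_only_post")


@dataclass
class EphysTrace:
    """Clamp-current time series with labeled epoch intervals (seconds).

    Inward current is negative.  Epochs must be non-overlapping; the washout
    epoch may be labeled ``gaba_only_post`` or ``washout``.
    """

    time_s: np.ndarray
    current_na: np.ndarray
    sampling_hz: float
    epochs: Mapping[str, tuple[float, float]]
    oocyte_id: str = ""
    treatment: str = ""
    holding_mv: float = -60.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.current_na = np.asarray(self.current_na, dtype=float)
        if self.time_s.shape != self.current_na.shape or self.time_s.ndim != 1:
            raise ValueError("time and current must be matching 1-D arrays")
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        ivals = sorted(self.epochs.items(), key=lambda kv: kv[1][0])
        for (la, (a0, a1)), (lb, (b0, b1)) in zip(ivals, ivals[1:]):
            if b0 < a1:
                raise ValueError(f"epochs {la!r} and {lb!r} overlap")
        for lab, (t0, t1) in self.epochs.items():
            if t1 <= t0:
                raise ValueError(f"epoch {lab!r} has non-positive duration")

    def epoch_samples(self, label: str) -> np.ndarray:
        if label not in self.epochs:
            raise KeyError(f"trace has no epoch {label!r}")
        t0, t1 = self.epochs[label]
        mask = (self.time_s >= t0) & (self.time_s < t1)
        return self.current_na[mask]


def _epoch_label(trace: EphysTrace, *candidates: str) -> str:
    for c in candidates:
        if c in trace.epochs:
            return c
    raise KeyError(f"trace has none of epochs {candidates}")


def leak_qc(trace: EphysTrace, limit_na: float = -1000.0) -> bool:
    """Pass unless the mean baseline (leak) current is *more negative* than the
    limit; a baseline of exactly -1000 nA still passes (strict 'excessive')."""
    base = trace.epoch_samples(_epoch_label(trace, "baseline"))
    return bool(base.mean() >= limit_na)


def epoch_amplitude(trace: EphysTrace, epoch: str, steady_s: float = 1.0) -> float:
    """Magnitude (nA) of the inward current in an epoch.

    Steady-state convention: mean over the final ``steady_s`` seconds of the
    epoch, minus the same measure of the baseline epoch.
    """
    t0, t1 = trace.epochs[epoch]
    if t1 - t0 < steady_s:
        raise ValueError(f"epoch {epoch!r} shorter than the {steady_s} s window")

    def steady(label: str) -> float:
        a0, a1 = trace.epochs[label]
        mask = (trace.time_s >= a1 - steady_s) & (trace.time_s < a1)
        vals = trace.current_na[mask]
        if vals.size == 0:
            raise ValueError(f"no samples in the steady window of epoch {label!r}")
        return float(vals.mean())

    return abs(steady(epoch) - steady("baseline"))


def rundown_fraction(control_traces: Sequence[EphysTrace]) -> float:
    """Mean fractional loss of GABA response on untreated control oocytes:
    ``1 - amplitude(post) / amplitude(pre)``, floored at 0."""
    if not control_traces:
        raise ValueError("need at least one control trace")
    losses = []
    for tr in control_traces:
        pre = epoch_amplitude(tr, _epoch_label(tr, "gaba_only_pre"))
        post = epoch_amplitude(tr, _epoch_label(tr, "gaba_only_post", "washout"))
        if pre == 0:
            raise ValueError(
                f"control {tr.oocyte_id!r} has zero pre-application amplitude"
            )
        losses.append(1.0 - post / pre)
    return max(0.0, float(np.mean(losses)))


def percent_block(
    trace: EphysTrace,
    rundown: float = 0.0,
    *,
    mode: str = "divide",
    leak_limit_na: float = -1000.0,
) -> float:
    """Rundown-adjusted percent block of the GABA-evoked current, in [0, 100].

    ``remaining = I_coapp / I_pre``; in the default multiplicative mode the
    adjusted remaining fraction is ``remaining / (1 - rundown)`` (rundown is a
    multiplicative amplitude loss); ``mode="subtract"`` instead adds the
    rundown percentage points back, for sensitivity analysis.
    """
    if not 0.0 <= rundown < 1.0:
        raise ValueError("rundown must be in [0, 1)")
    if not leak_qc(trace, leak_limit_na):
        raise ValueError(
            f"trace {trace.oocyte_id!r} fails leak QC (baseline beyond {leak_limit_na} nA)"
        )
    pre = epoch_amplitude(trace, _epoch_label(trace, "gaba_only_pre"))
    coapp = epoch_amplitude(trace, _epoch_label(trace, "coapplication"))
    if pre == 0:
        raise ValueError("zero pre-coapplication amplitude")
    remaining = coapp / pre
    if mode == "divide":
        adjusted = remaining / (1.0 - rundown)
    elif mode == "subtract":
        adjusted = remaining + rundown
    else:
        raise ValueError(f"unknown rundown mode {mode!r}")
    return float(np.clip(100.0 * (1.0 - adjusted), 0.0, 100.0))


@dataclass
class BlockResult:
    """Per-compound summary of oocyte percent-block measurements."""

    compound_id: str
    per_oocyte: tuple[float, ...]
    mean: float
    sem: Optional[float]
    n: int
    rundown_applied: float


def aggregate_block(
    blocks: Mapping[str, Sequence[float]], rundown: float = 0.0
) -> list[BlockResult]:
    """Mean +/- SEM percent block per compound.

    Oocyte counts outside the 3-6 design range trigger a warning but the
    computation proceeds; with a single oocyte the SEM is reported missing.
    """
    out = []
    for cid, vals in blocks.items():
        arr = np.asarray(list(vals), dtype=float)
        n = arr.size
        if n == 0:
            raise ValueError(f"no measurements for compound {cid!r}")
        if not 3 <= n <= 6:
            warnings.warn(
                f"compound {cid!r}: {n} oocytes is outside the 3-6 design range",
                stacklevel=2,
            )
        sem = float(stats.sem(arr, ddof=1)) if n >= 2 else None
        out.append(
            BlockResult(
                compound_id=cid,
                per_oocyte=tuple(arr),
                mean=float(arr.mean()),
                sem=sem,
                n=n,
                rundown_applied=rundown,
            )
        )
    return out


# ---------------------------------------------------------------------------
# insect mortality and LC50
# ---------------------------------------------------------------------------

def well_mortality(per_larva_outcomes: Sequence[bool]) -> bool:
    """Least-affected-individual rule: the well is dead only if every larva is."""
    outcomes = list(per_larva_outcomes)
    if not outcomes:
        raise ValueError("empty well")
    return all(outcomes)


@dataclass
class LC50Fit:
    """Maximum-likelihood log-logistic dose-response fit on binary well outcomes."""

    lc50: float
    slope: float
    loglik: float
    ci_low: float
    ci_high: float
    converged: bool
    n_wells: int
    model: str = "loglogistic"


_SLOPE_BOUNDS = (np.log(0.05), np.log(50.0))


def _nll(log_lc50: float, log_slope: float, logd: np.ndarray, dead: np.ndarray,
         n_larvae: np.ndarray, background: float = 0.0, probit: bool = False) -> float:
    s = np.exp(log_slope)
    eta = s * (logd - log_lc50)
    p = stats.norm.cdf(eta) if probit else special.expit(eta)
    if background > 0:  # Abbott correction: observed = bg + (1-bg) * p
        p = background + (1.0 - background) * p
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    # least-affected-individual rule: a well is dead iff all its larvae are
    p_well = np.clip(p**n_larvae, 1e-300, 1.0 - 1e-12)
    return float(-(dead * np.log(p_well) + (1 - dead) * np.log1p(-p_well)).sum())


def fit_lc50(
    table: pd.DataFrame,
    *,
    model: str = "loglogistic",
    background_mortality: float = 0.0,
    ci_level: float = 0.95,
) -> LC50Fit:
    """Maximum-likelihood log-logistic LC50 on well-level binary outcomes.

    The per-larva death probability is ``p = F(slope x (log dose - log LC50))``
    with ``F`` the logistic CDF (asymptotes fixed at 0 and 1) or, with
    ``model="probit"``, the normal CDF.  Because a well is scored dead only
    when its least-affected larva is dead, the well-level likelihood uses
    ``P(well dead) = p ** n_larvae`` when the table carries an ``n_larvae``
    column (exponent 1 otherwise), so the reported LC50 is the per-larva
    median lethal dose, not the inflated all-larvae-dead dose.  The table
    needs ``dose_ug_per_well`` and either ``well_dead`` or
    ``n_dead``/``n_larvae`` (from which the least-affected-individual rule
    derives the well outcome).  The CI is profile-likelihood on log LC50.
    Background (Abbott) correction is off by default: the assay design
    includes diluent checks, and no natural background mortality is assumed.

    Degenerate tables (no mortality variation, fewer than two distinct doses)
    yield ``converged=False`` with NaN estimates rather than a fabricated fit.
    """
    if "dose_ug_per_well" not in table.columns:
        raise ValueError("table must have a dose_ug_per_well column")
    if "well_dead" in table.columns:
        dead = table["well_dead"].astype(bool).to_numpy()
    elif {"n_dead", "n_larvae"}.issubset(table.columns):
        dead = (table["n_dead"] == table["n_larvae"]).to_numpy()
    else:
        raise ValueError("table needs well_dead or n_dead/n_larvae columns")
    doses = table["dose_ug_per_well"].to_numpy(dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if np.unique(doses).size < 2:
        raise ValueError("need at least two distinct doses")
    dead = dead.astype(float)
    n = dead.size
    if dead.sum() == 0 or dead.sum() == n:
        return LC50Fit(np.nan, np.nan, np.nan, np.nan, np.nan, False, n, model)
    if "n_larvae" in table.columns:
        n_larvae = table["n_larvae"].to_numpy(dtype=float)
        if np.any(n_larvae < 1):
            raise ValueError("n_larvae must be at least 1")
    else:
        n_larvae = np.ones(n)

    logd = np.log(doses)
    probit = model == "probit"
    x0 = np.array([float(np.median(logd)), np.log(2.0)])
    res = optimize.minimize(
        lambda th: _nll(th[0], th[1], logd, dead, n_larvae, background_mortality, probit),
        x0,
        method="L-BFGS-B",
        bounds=[(None, None), _SLOPE_BOUNDS],
    )
    log_lc50_hat, log_slope_hat = res.x
    nll_hat = float(res.fun)

    def profile_nll(log_lc50: float) -> float:
        r = optimize.minimize_scalar(
            lambda ls: _nll(log_lc50, ls, logd, dead, n_larvae,
                            background_mortality, probit),
            bounds=_SLOPE_BOUNDS,
            method="bounded",
        )
        return float(r.fun)

    crit = stats.chi2.ppf(ci_level, df=1) / 2.0

    def ci_bound(direction: float) -> float:
        span = np.ptp(logd) + np.log(100.0)
        f = lambda x: profile_nll(x) - nll_hat - crit
        lo, hi = log_lc50_hat, log_lc50_hat + direction * span
        if f(hi) < 0:
            return float(np.exp(hi)) if direction > 0 else float(np.exp(hi))
        a, b = (lo, hi) if direction > 0 else (hi, lo)
        try:
            root = optimize.brentq(f, a, b, xtol=1e-6)
        except ValueError:
            return np.nan
        return float(np.exp(root))

    ci_low, ci_high = ci_bound(-1.0), ci_bound(+1.0)
    return LC50Fit(
        lc50=float(np.exp(log_lc50_hat)),
        slope=float(np.exp(log_slope_hat)),
        loglik=-nll_hat,
        ci_low=ci_low,
        ci_high=ci_high,
        converged=bool(res.success),
        n_wells=n,
        model=model,
    )
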