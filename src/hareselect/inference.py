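"""Bootstrap inference over per-hare electivity values.

For each food item the per-hare epsilon values are resampled with
replacement (B times, default 1000) and a bias-corrected and accelerated
(BCa) confidence interval of the mean is computed. The bias-correction
constant z0 comes from the fraction of bootstrap means below the observed
mean (ties counted half, which keeps z0 finite on discrete data); the
acceleration a from the jackknife skewness

    a = sum(d_i^3) / (6 * (sum(d_i^2))^(3/2)),   d_i = mean(jack) - jack_i.

Adjusted endpoint percentiles are Phi(z0 + (z0 + z_alpha)/(1 - a*(z0 +
z_alpha))) and the interval is read off the empirical bootstrap-mean
distribution by linear interpolation between order statistics.

Selection is significant when both CI bounds share a sign: preference if
the lower bound is above 0, avoidance if the upper bound is below 0; an
interval touching 0 at either bound is classified "none". Items enter the
bootstrap only if at least ``min_n`` hares contribute (default 7).

Reproducibility: every item gets its own random substream derived from the
master seed and a stable hash of (scheme, item, stratum), so adding or
removing an item never perturbs another item's interval.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import ndtr, ndtri

from .config import AnalysisConfig
from .errors import ValidationError

logger = logging.getLogger(__name__)

STRATA_VARIABLES = ("all", "season", "sex", "age")

PREFERENCE = "preference"
AVOIDANCE = "avoidance"
NONE = "none"


@dataclass(frozen=True)
class BootstrapSummary:
    """Bootstrap result for one item within one stratum."""

    scheme: str
    item: str
    stratum: str
    n: int
    mean_epsilon: float
    ci_low: float
    ci_high: float
    significant: str
    B: int
    ci_level: float
    seed: int


@dataclass(frozen=True)
class SkippedStratum:
    """An item × stratum combination not bootstrapped, with the reason."""

    scheme: str
    item: str
    stratum: str
    n: int
    reason: str


def substream_seed(master_seed: int, scheme: str, item: str, stratum: str) -> np.random.SeedSequence:
    """Deterministic per-item substream independent of other items."""
    digest = hashlib.blake2b(
        f"{scheme}|{item}|{stratum}".encode("utf-8"), digest_size=4
    ).digest()
    return np.random.SeedSequence([int(master_seed) % 2**31, int.from_bytes(digest, "big")])


def _jackknife_acceleration(values: np.ndarray) -> float:
    n = values.size
    total = values.sum()
    jack = (total - values) / (n - 1)
    d = jack.mean() - jack
    denom = (d**2).sum() ** 1.5
    if denom == 0:
        return 0.0
    return float((d**3).sum() / (6.0 * denom))


def _adjusted_percentiles(z0: float, a: float, level: float) -> tuple[float, float]:
    """BCa endpoint percentiles; equals (alpha/2, 1-alpha/2) when z0=a=0."""
    alphas = []
    for tail in ((1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0):
        z = z0 + ndtri(tail)
        denom = 1.0 - a * z
        adj = z0 + z / denom if denom > 0 else np.inf * np.sign(z)
        alphas.append(float(np.clip(ndtr(adj), 0.0, 1.0)))
    return alphas[0], alphas[1]


def bca_interval(
    values: Sequence[float],
    B: int = 1000,
    level: float = 0.95,
    seed: int | np.random.SeedSequence | None = None,
    rng: np.random.Generator | None = None,
    *,
    z0_override: float | None = None,
    acceleration_override: float | None = None,
    return_diagnostics: bool = False,
):
    """BCa confidence interval for the mean of ``values``.

    Returns ``(ci_low, ci_high)``, or a diagnostics dict (including the
    bootstrap means, z0 and a) when ``return_diagnostics`` is set. The
    overrides pin z0 and/or a — with both set to 0 the interval reduces
    exactly to the percentile interval on the same resamples.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("bootstrap needs at least 2 values")
    if B < 100:
        raise ValidationError("B must be at least 100")
    if not (0.0 < level < 1.0):
        raise ValidationError("level must lie in (0, 1)")
    n = x.size
    obs = float(x.mean())
    if np.ptp(x) == 0:
        warnings.warn("all values identical: degenerate interval", stacklevel=2)
        obs = float(x[0])  # exact common value, not the rounded mean
        result = (obs, obs)
        if return_diagnostics:
            return {
                "interval": result, "z0": 0.0, "a": 0.0,
                "boot_means": np.full(B, obs), "observed_mean": obs,
            }
        return result
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    boot = x[idx].mean(axis=1)

    if z0_override is not None:
        z0 = float(z0_override)
    else:
        below = np.count_nonzero(boot < obs)
        ties = np.count_nonzero(boot == obs)
        p = (below + 0.5 * ties) / B
        p = min(max(p, 0.5 / B), 1.0 - 0.5 / B)  # keep z0 finite
        z0 = float(ndtri(p))
    a = float(acceleration_override) if acceleration_override is not None \
        else _jackknife_acceleration(x)
    lo_p, hi_p = _adjusted_percentiles(z0, a, level)
    ci_low, ci_high = (float(q) for q in np.quantile(boot, [lo_p, hi_p]))
    if return_diagnostics:
        return {
            "interval": (ci_low, ci_high), "z0": z0, "a": a,
            "boot_means": boot, "observed_mean": obs,
            "percentiles": (lo_p, hi_p),
        }
    return ci_low, ci_high


def percentile_interval(
    values: Sequence[float],
    B: int = 1000,
    level: float = 0.95,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[float, float]:
    """Plain percentile bootstrap interval on the same resampling scheme."""
    return bca_interval(
        values, B=B, level=level, seed=seed,
        z0_override=0.0, acceleration_override=0.0,
    )


def classify_selection(ci_low: float, ci_high: float) -> str:
    """Same-sign rule: preference if both bounds > 0, avoidance if both < 0.

    A bound exactly at 0 carries no sign, so such intervals classify as
    "none".
    """
    if ci_low > ci_high:
        raise ValidationError("ci_low must not exceed ci_high")
    if ci_low > 0:
        return PREFERENCE
    if ci_high < 0:
        return AVOIDANCE
    return NONE


def _contributes(record, basis: str) -> bool:
    return record.alpha > 0 if basis == "used" else True


def eligible_items(records: Iterable, min_n: int, basis: str = "used") -> list[tuple[str, str]]:
    """(scheme, item) pairs with at least ``min_n`` contributing hares.

    Under the default basis "used" a hare contributes to an item when the
    item appears in its diet (use > 0, equivalently alpha > 0); under
    "available" every hare with a record for the item contributes.
    """
    if min_n < 1:
        raise ValidationError("min_n must be a positive integer")
    counts: dict[tuple[str, str], set] = {}
    for rec in records:
        if _contributes(rec, basis):
            counts.setdefault((rec.scheme, rec.item), set()).add(rec.hare_id)
    return sorted(k for k, hares in counts.items() if len(hares) >= min_n)


def _stratum_label(record, variable: str) -> str:
    if variable == "all":
        return "all"
    return f"{variable}:{getattr(record, variable)}"


def stratified_summaries(
    records: Iterable,
    strata: Sequence[str] = ("all",),
    config: AnalysisConfig | None = None,
) -> tuple[list[BootstrapSummary], list[SkippedStratum]]:
    """Bootstrap every eligible item within every requested stratification.

    ``strata`` lists stratification variables from {all, season, sex, age};
    "all" is the unstratified analysis. Item × stratum combinations with
    fewer than ``min_n`` contributing hares are reported in the skipped
    list with the reason rather than silently dropped.
    """
    config = config or AnalysisConfig()
    records = list(records)
    for variable in strata:
        if variable not in STRATA_VARIABLES:
            raise ValidationError(f"unknown stratification variable {variable!r}")
    summaries: list[BootstrapSummary] = []
    skipped: list[SkippedStratum] = []
    for variable in strata:
        cells: dict[tuple[str, str, str], list] = {}
        for rec in records:
            label = _stratum_label(rec, variable)
            cells.setdefault((rec.scheme, rec.item, label), []).append(rec)
        for (scheme, item, label), recs in sorted(cells.items()):
            contributing = [r for r in recs if _contributes(r, config.eligibility_basis)]
            n = len({r.hare_id for r in contributing})
            if n < config.min_n:
                skipped.append(SkippedStratum(scheme, item, label, n, f"n < min_n ({n} < {config.min_n})"))
                continue
            if n < 2:
                skipped.append(SkippedStratum(scheme, item, label, n, "n < 2: no resampling possible"))
                continue
            values = np.array([r.epsilon for r in contributing])
            ss = substream_seed(config.rng_seed, scheme, item, label)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # degenerate-interval warning is recorded in the CI itself
                ci_low, ci_high = bca_interval(
                    values, B=config.bootstrap_B, level=config.ci_level, seed=ss
                )
            summaries.append(
                BootstrapSummary(
                    scheme=scheme,
                    item=item,
                    stratum=label,
                    n=n,
                    mean_epsilon=float(values.mean()),
                    ci_low=ci_low,
                    ci_high=ci_high,
                    significant=classify_selection(ci_low, ci_high),
                    B=config.bootstrap_B,
                    ci_level=config.ci_level,
                    seed=config.rng_seed,
                )
            )
    return summaries, skipped
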