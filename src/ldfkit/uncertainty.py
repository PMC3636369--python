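"""Monte Carlo propagation of parameter uncertainty and rank sensitivity.

Time-independent parameters carry a best estimate (BE) for deterministic
baseline runs and, where uncertain, a probability density function for
probabilistic runs.  Simple random sampling drives repeated end-to-end LDF
computations; sensitivity is Spearman rank correlation between each sampled
parameter and the LDF (robust to the log-scale spread of Kd/CR values).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .nuclides import ValidationError

log = logging.getLogger(__name__)

DistributionKind = Literal[
    "constant", "uniform", "loguniform", "triangular", "normal", "lognormal"
]


class ParameterDistribution(BaseModel):
    """PDF (or constant) for one dotted parameter path in a config.

    ``params`` holds the distribution parameters: uniform/loguniform use
    ``low``/``high``; triangular ``low``/``mode``/``high``; normal and
    lognormal ``mu``/``sigma`` (of the log for lognormal) plus optional
    truncation bounds ``low``/``high``.
    """

    path: str
    kind: DistributionKind
    params: dict[str, float] = Field(default_factory=dict)
    best_estimate: float

    @model_validator(mode="after")
    def _check(self) -> "ParameterDistribution":
        p, be = self.params, self.best_estimate
        if self.kind in ("uniform", "loguniform", "triangular"):
            if not p.get("low", 0.0) <= be <= p.get("high", 0.0):
                raise ValueError(
                    f"{self.path}: best estimate {be} outside [{p.get('low')}, {p.get('high')}]"
                )
            if self.kind == "loguniform" and p.get("low", 0.0) <= 0.0:
                raise ValueError(f"{self.path}: loguniform requires low > 0")
            if self.kind == "triangular" and not (
                p["low"] <= p["mode"] <= p["high"]
            ):
                raise ValueError(f"{self.path}: triangular needs low <= mode <= high")
        if self.kind in ("normal", "lognormal"):
            if p.get("sigma", 1.0) < 0.0:
                raise ValueError(f"{self.path}: sigma must be >= 0")
            lo, hi = p.get("low", -np.inf), p.get("high", np.inf)
            if not lo <= be <= hi:
                raise ValueError(f"{self.path}: best estimate outside truncation bounds")
        return self

    def sample(self, rng: np.random.Generator) -> float:
        p = self.params
        if self.kind == "constant":
            return self.best_estimate
        if self.kind == "uniform":
            return float(rng.uniform(p["low"], p["high"]))
        if self.kind == "loguniform":
            return float(np.exp(rng.uniform(np.log(p["low"]), np.log(p["high"]))))
        if self.kind == "triangular":
            return float(rng.triangular(p["low"], p["mode"], p["high"]))
        lo, hi = p.get("low", -np.inf), p.get("high", np.inf)
        for _ in range(1000):
            if self.kind == "normal":
                x = float(rng.normal(p["mu"], p["sigma"]))
            else:
                x = float(np.exp(rng.normal(p["mu"], p["sigma"])))
            if lo <= x <= hi:
                return x
        raise ValidationError(f"{self.path}: truncated sampling failed to converge")

    def ppf(self, q: float) -> float:
        """Inverse CDF, used by Latin hypercube sampling."""
        p = self.params
        if self.kind == "constant":
            return self.best_estimate
        if self.kind == "uniform":
            return p["low"] + q * (p["high"] - p["low"])
        if self.kind == "loguniform":
            lo, hi = np.log(p["low"]), np.log(p["high"])
            return float(np.exp(lo + q * (hi - lo)))
        if self.kind == "triangular":
            lo, mode, hi = p["low"], p["mode"], p["high"]
            width = hi - lo
            if width == 0.0:
                return lo
            c = (mode - lo) / width
            return float(stats.triang.ppf(q, c, loc=lo, scale=width))
        mu, sigma = p["mu"], p["sigma"]
        lo, hi = p.get("low", -np.inf), p.get("high", np.inf)
        if self.kind == "lognormal":
            lo = np.log(lo) if lo > 0.0 else -np.inf
            hi = np.log(hi) if np.isfinite(hi) else np.inf
        if np.isfinite(lo) or np.isfinite(hi):
            a, b = (lo - mu) / sigma, (hi - mu) / sigma
            x = float(stats.truncnorm.ppf(q, a, b, loc=mu, scale=sigma))
        else:
            x = float(stats.norm.ppf(q, loc=mu, scale=sigma))
        return float(np.exp(x)) if self.kind == "lognormal" else x


def sample_parameters(
    distributions: list[ParameterDistribution],
    n: int,
    seed: int,
    method: str = "srs",
) -> pd.DataFrame:
    """n sampled parameter sets, one column per path.

    ``method="srs"`` (default) is simple random sampling: reproducible for
    a given seed, with rows drawn one full parameter set at a time so the
    first half of a 2n-draw with the same seed equals the n-draw
    (stream-prefix property).  ``method="lhs"`` stratifies each marginal
    with a Latin hypercube (no stream-prefix property).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if method == "srs":
        rng = np.random.default_rng(seed)
        rows = [
            {dist.path: dist.sample(rng) for dist in distributions} for _ in range(n)
        ]
        return pd.DataFrame(rows)
    if method == "lhs":
        sampler = stats.qmc.LatinHypercube(d=len(distributions), seed=seed)
        unit = sampler.random(n)
        return pd.DataFrame(
            {
                dist.path: [dist.ppf(q) for q in unit[:, j]]
                for j, dist in enumerate(distributions)
            }
        )
    raise ValidationError(f"unknown sampling method {method!r}")


@dataclass
class ProbabilisticResult:
    samples: pd.DataFrame  # parameter columns + "ldf"
    baseline_ldf: float
    summary: dict
    failures: list[tuple[int, str]]


def run_probabilistic(
    ldf_for_overrides: Callable[[dict[str, float]], float],
    distributions: list[ParameterDistribution],
    n: int,
    seed: int,
) -> ProbabilisticResult:
    """n independent end-to-end LDF evaluations over sampled parameters.

    ``ldf_for_overrides`` maps a {path: value} override dict to an LDF; the
    empty dict is the deterministic best-estimate baseline.  Individual run
    failures are recorded, excluded and counted.
    """
    baseline = ldf_for_overrides({})
    samples = sample_parameters(distributions, n, seed)
    ldfs = np.full(n, np.nan)
    failures: list[tuple[int, str]] = []
    for i in range(n):
        overrides = samples.iloc[i].to_dict()
        try:
            ldfs[i] = ldf_for_overrides(overrides)
        except Exception as exc:  # record, exclude, continue
            failures.append((i, repr(exc)))
            log.warning("probabilistic run %d failed: %r", i, exc)
    samples = samples.assign(ldf=ldfs)
    ok = samples["ldf"].dropna()
    summary = {
        "n": n,
        "n_failed": len(failures),
        "baseline_ldf": baseline,
        "mean": float(ok.mean()),
        "median": float(ok.median()),
        "p5": float(ok.quantile(0.05)),
        "p95": float(ok.quantile(0.95)),
    }
    return ProbabilisticResult(
        samples=samples, baseline_ldf=baseline, summary=summary, failures=failures
    )


def rank_sensitivity(
    parameter_samples: pd.DataFrame,
    ldf_samples: pd.Series | np.ndarray,
    metric: str = "spearman",
) -> pd.DataFrame:
    """Rank-based sensitivity of the LDF to each sampled parameter.

    ``metric="spearman"`` (default, robust to the log-scale spread of
    Kd/CR) reports the Spearman rank correlation per parameter;
    ``metric="srrc"`` reports standardized rank regression coefficients
    from a joint linear fit on the ranks.  Ties get average ranks;
    constant parameter columns are reported with rho = 0 and flagged.
    Sorted by |rho| descending.
    """
    ldf = np.asarray(ldf_samples, dtype=float)
    if len(ldf) < 50:
        raise ValidationError("rank sensitivity needs at least 50 samples")
    if metric not in ("spearman", "srrc"):
        raise ValidationError(f"unknown sensitivity metric {metric!r}")
    mask = np.isfinite(ldf)
    varying = [
        c
        for c in parameter_samples.columns
        if not np.all(
            parameter_samples[c].to_numpy(dtype=float)[mask]
            == parameter_samples[c].to_numpy(dtype=float)[mask][0]
        )
    ]
    records = []
    srrc_coeffs: dict[str, float] = {}
    if metric == "srrc" and varying:
        ranks_x = np.column_stack(
            [stats.rankdata(parameter_samples[c].to_numpy(dtype=float)[mask])
             for c in varying]
        )
        ranks_y = stats.rankdata(ldf[mask])
        zx = (ranks_x - ranks_x.mean(axis=0)) / ranks_x.std(axis=0, ddof=1)
        zy = (ranks_y - ranks_y.mean()) / ranks_y.std(ddof=1)
        beta, *_ = np.linalg.lstsq(zx, zy, rcond=None)
        srrc_coeffs = dict(zip(varying, beta))
    for column in parameter_samples.columns:
        if column not in varying:
            records.append({"parameter": column, "rho": 0.0, "constant": True})
            continue
        if metric == "spearman":
            x = parameter_samples[column].to_numpy(dtype=float)[mask]
            rho = float(stats.spearmanr(x, ldf[mask]).statistic)
        else:
            rho = float(srrc_coeffs[column])
        records.append({"parameter": column, "rho": rho, "constant": False})
    table = pd.DataFrame(records)
    return table.reindex(
        table["rho"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
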