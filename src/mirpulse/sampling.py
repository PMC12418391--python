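"""Global and local sensitivity analysis of the frequency-response metrics.

This module is the study's synthetic-input generator: kinetic parameter sets
are drawn log-uniformly by Latin Hypercube sampling (one draw per
equal-probability stratum per dimension), each set is pushed through the
frequency-response pipeline, and partial rank correlation coefficients
(PRCC) quantify how strongly each parameter drives the advantage A, the
selectivity S, the preferred frequency f*, and (for two competing targets)
the differential selectivity DS.  Local structure is probed by pairwise
log-spaced parameter grids and by scans over initial conditions.

Default sampling ranges ship as a config file (``data/default_ranges.yaml``)
spanning biologically plausible orders of magnitude; studies with their own
kinetic estimates should supply their own ranges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.stats import qmc, rankdata

from .errors import DegenerateEquilibrationError, MirpulseError, ParameterError
from .metrics import (
    differential_selectivity,
    frequency_response,
    frequency_response_pair,
    metric_set,
)
from .models import FAST_SOLVER, ParamsM1, ParamsM2, SolverSettings

__all__ = [
    "ParameterRanges",
    "default_ranges",
    "lhs_loguniform",
    "evaluate_samples",
    "prcc",
    "prcc_table",
    "ds_ratio_prcc",
    "pairwise_grid_scan",
    "initial_condition_scan",
]

logger = logging.getLogger(__name__)

_M1_FIELDS = ("sigma", "kappa_on", "kappa_off", "alpha", "beta", "gamma")
_M2_FIELDS = (
    "sigma",
    "gamma",
    "kappa_on_1",
    "kappa_off_1",
    "alpha_1",
    "beta_1",
    "kappa_on_2",
    "kappa_off_2",
    "alpha_2",
    "beta_2",
    "delta",
    "epsilon",
)
_COMPETITOR_FIELDS = ("kappa_on_2", "kappa_off_2", "alpha_2", "beta_2", "delta", "epsilon")


def _load_default_ranges() -> dict:
    text = resources.files("mirpulse.data").joinpath("default_ranges.yaml").read_text()
    raw = yaml.safe_load(text)
    return {
        model: {k: (float(lo), float(hi)) for k, (lo, hi) in spec.items()}
        for model, spec in raw.items()
    }


def default_ranges() -> dict:
    """The packaged default log-uniform ranges, keyed by model id."""
    return _load_default_ranges()


@dataclass(frozen=True)
class ParameterRanges:
    """Sampling specification: per-parameter (lo, hi) bounds plus frozen values.

    Sampled parameters are drawn log-uniformly within their bounds; frozen
    parameters are held at an explicit value (by convention the geometric
    mean of their default range — the median of a log-uniform draw).
    """

    model_id: str
    ranges: dict = field(default_factory=dict)
    frozen: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        fields_ = _M1_FIELDS if self.model_id == "M1" else _M2_FIELDS
        if self.model_id not in ("M1", "M2"):
            raise ParameterError(f"unknown model_id {self.model_id!r}")
        for name, (lo, hi) in self.ranges.items():
            if name not in fields_:
                raise ParameterError(f"unknown parameter {name!r} for model {self.model_id}")
            if not (0 < lo < hi):
                raise ParameterError(
                    f"log-uniform bounds require 0 < lo < hi for {name}, got ({lo}, {hi})"
                )
        for name in self.frozen:
            if name not in fields_:
                raise ParameterError(f"unknown frozen parameter {name!r}")
        missing = set(fields_) - set(self.ranges) - set(self.frozen)
        if missing:
            raise ParameterError(f"parameters neither sampled nor frozen: {sorted(missing)}")

    @property
    def sampled_names(self) -> tuple:
        fields_ = _M1_FIELDS if self.model_id == "M1" else _M2_FIELDS
        return tuple(n for n in fields_ if n in self.ranges)

    def geometric_medians(self) -> dict:
        """Geometric mean of each sampled range, merged with frozen values."""
        out = {n: math.sqrt(lo * hi) for n, (lo, hi) in self.ranges.items()}
        out.update(self.frozen)
        return out

    def median_params(self):
        return self.make_params(self.geometric_medians())

    def make_params(self, values: dict):
        merged = {**self.frozen, **values}
        if self.model_id == "M1":
            return ParamsM1(**{k: merged[k] for k in _M1_FIELDS})
        return ParamsM2(**{k: merged[k] for k in _M2_FIELDS})

    # -- canned study designs ------------------------------------------------

    @classmethod
    def m1(cls) -> "ParameterRanges":
        """Sample every M1 parameter (global sensitivity study)."""
        return cls("M1", ranges=default_ranges()["M1"])

    @classmethod
    def m2_competitor(cls) -> "ParameterRanges":
        """Freeze the miRNA/R1 parameters at their geometric medians and
        sample only the competitor's (the ceRNA crosstalk study)."""
        full = default_ranges()["M2"]
        ranges = {k: full[k] for k in _COMPETITOR_FIELDS}
        frozen = {
            k: math.sqrt(lo * hi)
            for k, (lo, hi) in full.items()
            if k not in _COMPETITOR_FIELDS
        }
        return cls("M2", ranges=ranges, frozen=frozen)

    @classmethod
    def m2_full(cls) -> "ParameterRanges":
        """Sample the complete M2 parameter space (differential-selectivity study)."""
        return cls("M2", ranges=default_ranges()["M2"])


def lhs_loguniform(ranges: ParameterRanges, n: int, seed: int) -> pd.DataFrame:
    """Latin Hypercube draw of ``n`` parameter sets, log-uniform per dimension.

    For each sampled dimension the n values occupy n equal-probability strata
    in log10 space, one value per stratum, with independent random stratum
    permutations across dimensions; identical seeds reproduce the table
    bitwise.
    """
    if n < 2:
        raise ParameterError(f"n must be >= 2, got {n}")
    names = ranges.sampled_names
    sampler = qmc.LatinHypercube(d=len(names), seed=np.random.default_rng(seed))
    unit = sampler.random(n)
    data = {}
    for j, name in enumerate(names):
        lo, hi = ranges.ranges[name]
        data[name] = lo * (hi / lo) ** unit[:, j]
    df = pd.DataFrame(data)
    df.index.name = "sample"
    return df


def evaluate_samples(
    samples: pd.DataFrame,
    ranges: ParameterRanges,
    study: str = "auto",
    duty: float = 0.5,
    n_max: int = 25,
    rel_tol: float = 0.01,
    solver: SolverSettings = FAST_SOLVER,
) -> pd.DataFrame:
    """Run the frequency-response pipeline for every sampled parameter set.

    ``study`` selects the outputs: ``"m1"`` computes (A, S, f_star) of the
    single target; ``"m2_competitor"`` computes the first target's metrics
    (A1, S1, f_star1) under sampled competitor kinetics; ``"m2_full"``
    additionally computes the second target's metrics and DS on R1's window.
    Each row gets its own equilibration window tau (recomputed from its own
    sigma_const). Failed rows (solver failure, degenerate equilibration) are
    dropped from the result with a logged count, recorded in
    ``result.attrs["n_excluded"]`` and ``result.attrs["excluded_index"]``.
    """
    if study == "auto":
        study = "m1" if ranges.model_id == "M1" else (
            "m2_competitor" if ranges.frozen else "m2_full"
        )
    if study not in ("m1", "m2_competitor", "m2_full"):
        raise ParameterError(f"unknown study {study!r}")

    rows = []
    excluded = []
    for idx, row in samples.iterrows():
        values = row.to_dict()
        try:
            params = ranges.make_params(values)
            if study == "m1":
                resp = frequency_response(
                    "M1", params, duty=duty, n_max=n_max, rel_tol=rel_tol, solver=solver
                )
                ms = metric_set(resp)
                out = {
                    "A": ms.advantage,
                    "S": ms.selectivity,
                    "f_star": ms.preferred_frequency,
                    "fr_const": resp.fr_const,
                    "tau": resp.tau,
                }
            elif study == "m2_competitor":
                resp = frequency_response(
                    "M2", params, duty=duty, n_max=n_max, rel_tol=rel_tol, solver=solver
                )
                ms = metric_set(resp)
                out = {
                    "A1": ms.advantage,
                    "S1": ms.selectivity,
                    "f_star1": ms.preferred_frequency,
                    "fr_const1": resp.fr_const,
                    "tau": resp.tau,
                }
            else:
                resp1, resp2 = frequency_response_pair(
                    params, duty=duty, n_max=n_max, rel_tol=rel_tol, solver=solver
                )
                ms1, ms2 = metric_set(resp1), metric_set(resp2)
                out = {
                    "A1": ms1.advantage,
                    "S1": ms1.selectivity,
                    "f_star1": ms1.preferred_frequency,
                    "A2": ms2.advantage,
                    "S2": ms2.selectivity,
                    "f_star2": ms2.preferred_frequency,
                    "DS": differential_selectivity(resp1, resp2),
                    "tau": resp1.tau,
                }
        except MirpulseError as exc:
            excluded.append((idx, str(exc)))
            continue
        rows.append({**values, **out, "sample": idx})

    result = pd.DataFrame(rows).set_index("sample") if rows else pd.DataFrame()
    result.attrs["n_excluded"] = len(excluded)
    result.attrs["excluded_index"] = [i for i, _ in excluded]
    result.attrs["study"] = study
    result.attrs["valid"] = len(result) >= 0.95 * len(samples)
    if excluded:
        logger.warning("excluded %d/%d samples: %s", len(excluded), len(samples), excluded[:5])
    return result


# ---------------------------------------------------------------------------
# PRCC


def _rank(x: np.ndarray) -> np.ndarray:
    return rankdata(x, method="average")


def prcc(samples: pd.DataFrame, param_names, output_name: str) -> pd.Series:
    """Partial rank correlation of each parameter with one output.

    All columns are rank-transformed (average ranks on ties); the partial
    correlation between each parameter's ranks and the output's ranks,
    controlling for all other parameters' ranks, is read off the precision
    (inverse correlation) matrix: PRCC_j = -P[j, y] / sqrt(P[j, j] * P[y, y]).
    Rank-based, hence invariant under strictly monotone transforms of any
    input.
    """
    param_names = list(param_names)
    if len(samples) < 10:
        raise ParameterError(f"need >= 10 complete rows for PRCC, got {len(samples)}")
    cols = param_names + [output_name]
    mat = np.empty((len(samples), len(cols)))
    for j, c in enumerate(cols):
        x = samples[c].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ParameterError(f"column {c!r} contains non-finite values")
        if np.all(x == x[0]):
            raise ParameterError(f"column {c!r} is constant; PRCC undefined")
        mat[:, j] = _rank(x)
    corr = np.corrcoef(mat, rowvar=False)
    y = len(cols) - 1
    if np.linalg.cond(corr) < 1e10:
        prec = np.linalg.inv(corr)
        vals = [
            -prec[j, y] / math.sqrt(prec[j, j] * prec[y, y])
            for j in range(len(param_names))
        ]
    else:
        # near-singular rank correlations (e.g. an output that is a strictly
        # monotone function of one parameter): compute each coefficient by
        # explicit residual regressions instead of the precision matrix
        n = mat.shape[0]
        vals = []
        for j in range(len(param_names)):
            others = np.column_stack(
                [np.ones(n)] + [mat[:, k] for k in range(len(cols)) if k not in (j, y)]
            )
            bx, *_ = np.linalg.lstsq(others, mat[:, j], rcond=None)
            by, *_ = np.linalg.lstsq(others, mat[:, y], rcond=None)
            rx = mat[:, j] - others @ bx
            ry = mat[:, y] - others @ by
            vals.append(float(np.corrcoef(rx, ry)[0, 1]))
    return pd.Series(vals, index=param_names, name=output_name)


def prcc_table(samples: pd.DataFrame, param_names, output_names) -> pd.DataFrame:
    """PRCC of every (parameter, output) pair; outputs as rows, parameters as columns."""
    return pd.DataFrame(
        {out: prcc(samples, param_names, out) for out in output_names}
    ).T


def ds_ratio_prcc(samples: pd.DataFrame) -> pd.Series:
    """PRCC of DS against the derived kinetic ratios of the two targets.

    Covariates: the relative dissociation constant K2/K1 (with
    K_i = kappa_off_i / kappa_on_i), alpha2/alpha1, beta2/beta1, plus delta
    and epsilon. Requires a full M2 sampling with the DS column present.
    """
    needed = {"kappa_on_1", "kappa_on_2", "kappa_off_1", "kappa_off_2", "DS"}
    if not needed.issubset(samples.columns):
        raise ParameterError("ds_ratio_prcc requires a full M2 sample table with DS")
    df = samples.copy()
    df["K2_over_K1"] = (df["kappa_off_2"] / df["kappa_on_2"]) / (
        df["kappa_off_1"] / df["kappa_on_1"]
    )
    df["alpha2_over_alpha1"] = df["alpha_2"] / df["alpha_1"]
    df["beta2_over_beta1"] = df["beta_2"] / df["beta_1"]
    covs = ["K2_over_K1", "alpha2_over_alpha1", "beta2_over_beta1", "delta", "epsilon"]
    return prcc(df, covs, "DS")


# ---------------------------------------------------------------------------
# Grid scans


def pairwise_grid_scan(
    ranges: ParameterRanges,
    varied: tuple,
    resolution: int = 5,
    study: str = "auto",
    duty: float = 0.5,
    n_max: int = 25,
    rel_tol: float = 0.01,
    solver: SolverSettings = FAST_SOLVER,
) -> pd.DataFrame:
    """Metrics on a log-spaced grid of two parameters, all others at their
    geometric medians.

    For M1 (and the M2 competitor view) each cell carries (A, S, f_star);
    with ``study="m2_full"`` each cell carries both targets' metrics and DS.
    Failed cells are recorded in ``attrs`` and omitted.
    """
    p1, p2 = varied
    if p1 == p2:
        raise ParameterError("varied parameters must differ")
    if resolution < 1:
        raise ParameterError(f"resolution must be >= 1, got {resolution}")
    for p in (p1, p2):
        if p not in ranges.ranges:
            raise ParameterError(f"{p!r} has no sampling range to span")
    medians = ranges.geometric_medians()
    axes = {}
    for p in (p1, p2):
        lo, hi = ranges.ranges[p]
        axes[p] = (
            np.array([math.sqrt(lo * hi)])
            if resolution == 1
            else np.logspace(math.log10(lo), math.log10(hi), resolution)
        )
    if study == "auto":
        study = "m1" if ranges.model_id == "M1" else (
            "m2_full" if not ranges.frozen and ranges.model_id == "M2" else "m2_competitor"
        )

    rows, failed = [], []
    for v1 in axes[p1]:
        for v2 in axes[p2]:
            values = {**medians, p1: float(v1), p2: float(v2)}
            try:
                params = ranges.make_params(values)
                if study in ("m1", "m2_competitor"):
                    model_id = "M1" if ranges.model_id == "M1" else "M2"
                    resp = frequency_response(
                        model_id, params, duty=duty, n_max=n_max, rel_tol=rel_tol, solver=solver
                    )
                    ms = metric_set(resp)
                    out = {
                        "A": ms.advantage,
                        "S": ms.selectivity,
                        "f_star": ms.preferred_frequency,
                    }
                else:
                    resp1, resp2 = frequency_response_pair(
                        params, duty=duty, n_max=n_max, rel_tol=rel_tol, solver=solver
                    )
                    ms = metric_set(resp1)
                    out = {
                        "A": ms.advantage,
                        "S": ms.selectivity,
                        "f_star": ms.preferred_frequency,
                        "DS": differential_selectivity(resp1, resp2),
                    }
            except MirpulseError as exc:
                failed.append(((float(v1), float(v2)), str(exc)))
                continue
            rows.append({p1: float(v1), p2: float(v2), **out})
    df = pd.DataFrame(rows)
    df.attrs["failed_cells"] = failed
    df.attrs["varied"] = (p1, p2)
    return df


def initial_condition_scan(
    params: ParamsM1,
    resolution: int = 5,
    duty: float = 0.5,
    n_max: int = 25,
    rel_tol: float = 0.01,
    solver: SolverSettings = FAST_SOLVER,
) -> pd.DataFrame:
    """Metrics over a linear grid of initial conditions (R0, r0).

    R0 spans [0, 1] (up to the unrepressed target steady state) and r0 spans
    [0, sigma/gamma] (up to the miRNA's maximal interaction-free level), so
    the four corner cells are the canonical scenarios: both species starting
    from zero, a pre-expressed target, a pre-accumulated miRNA, and both
    pre-expressed. Cells whose target starts (and stays) at steady state are
    flagged as degenerate and carry NaN metrics rather than failing the scan.
    """
    R0s = np.linspace(0.0, 1.0, resolution)
    r0s = np.linspace(0.0, params.sigma / params.gamma, resolution)
    rows = []
    for R0 in R0s:
        for r0 in r0s:
            rec = {"R0": float(R0), "r0": float(r0)}
            try:
                resp = frequency_response(
                    "M1",
                    params,
                    duty=duty,
                    initial_state=np.array([R0, r0, 0.0]),
                    n_max=n_max,
                    rel_tol=rel_tol,
                    solver=solver,
                )
                ms = metric_set(resp)
                rec.update(
                    A=ms.advantage,
                    S=ms.selectivity,
                    f_star=ms.preferred_frequency,
                    degenerate=False,
                )
            except DegenerateEquilibrationError:
                rec.update(A=np.nan, S=np.nan, f_star=np.nan, degenerate=True)
            rows.append(rec)
    return pd.DataFrame(rows)
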