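"""Model qualification: goodness-of-fit tables, visual predictive checks and
the non-parametric bootstrap.

CWRES follows the standard FOCE-with-interaction definition: with G the
sensitivity of the prediction to eta at the conditional mode eta_hat, the
linearised marginal distribution of a subject's observations has mean
``f(eta_hat) - G eta_hat`` and covariance ``G Omega G' + diag(v)``; CWRES is
the Cholesky-whitened residual under that distribution, so for a correct
model it is approximately standard normal.

The VPC simulates replicate datasets under the fitted model on the original
design (doses, sampling times, covariates), bins observations by nominal
time after dose, and compares observed 5th/50th/95th percentiles with the
simulation-based confidence bands. Profiles are dose-normalised by default
because the pooled designs span 5–30 mg.

The bootstrap resamples subjects with replacement (stratified by study so
the design mix is preserved), refits each replicate warm-started from the
point estimates, and summarises parameter medians with percentile CIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .data import LLOQ
from .estimation import CovariateEffect, PopPKModel, PopPKResults

__all__ = [
    "gof_table",
    "VpcSummary",
    "vpc",
    "BootstrapSummary",
    "bootstrap",
    "plot_gof",
    "plot_vpc",
]


def _tad_and_dose(model: PopPKModel):
    """Per observation cell: time after the most recent dose start and that
    dose's amount (mg), arrays shaped like the padded time matrix."""
    b = model._batch
    times, mask = b["times"], b["obs_mask"]
    tad = np.zeros_like(times)
    amt = np.ones_like(times)
    for i in range(times.shape[0]):
        starts = b["start"][i][b["dose_mask"][i]]
        amts = b["amt"][i][b["dose_mask"][i]] / 1000.0  # back to mg
        idx = np.searchsorted(starts, times[i], side="right") - 1
        idx = np.clip(idx, 0, len(starts) - 1)
        tad[i] = times[i] - starts[idx]
        amt[i] = amts[idx]
    return np.where(mask, tad, np.nan), np.where(mask, amt, np.nan)


def gof_table(results: PopPKResults) -> pd.DataFrame:
    """Observation-level goodness-of-fit table.

    Columns: ID, TIME, TAD, DV, PRED (population prediction, eta = 0),
    IPRED (individual prediction at the empirical-Bayes etas) and CWRES.
    """
    model = results.model
    if results.ebes is None:
        raise ValueError("fit carries no empirical-Bayes estimates")
    b = model._batch
    values = results.params
    logbase = model._log_base(values)
    eta_hat = results.ebes.to_numpy()
    zeros = np.zeros_like(eta_hat)

    pred = model._f_eta(logbase, zeros)
    ipred = model._f_eta(logbase, eta_hat)
    G = model._jacobian(logbase, eta_hat)
    _, v, _, _ = model._residual_parts(ipred, values)
    omega2 = model._omega_values(values)

    tad, _ = _tad_and_dose(model)
    rows = []
    for i, sid in enumerate(b["ids"]):
        m = b["obs_mask"][i]
        Gi = G[i][m]                                   # (n_i, q)
        cov = Gi @ (omega2[:, None] * Gi.T) + np.diag(v[i][m])
        mean = ipred[i][m] - Gi @ eta_hat[i]
        L = np.linalg.cholesky(cov)
        cwres = solve_triangular(L, b["y"][i][m] - mean, lower=True)
        rows.append(pd.DataFrame({
            "ID": sid, "TIME": b["times"][i][m], "TAD": tad[i][m],
            "DV": b["y"][i][m], "PRED": pred[i][m], "IPRED": ipred[i][m],
            "CWRES": cwres}))
    return pd.concat(rows, ignore_index=True)


@dataclass
class VpcSummary:
    """Binned VPC table plus provenance (replicates, seed).

    ``table`` has one row per (bin, percentile) with the observed percentile
    and the simulated percentile's median and confidence limits."""

    table: pd.DataFrame
    n_replicates: int
    seed: int
    ci: float
    dose_normalized: bool

    def __post_init__(self) -> None:
        t = self.table
        for tad, grp in t.groupby("bin_tad"):
            med = grp.sort_values("percentile")["sim_median"].to_numpy()
            if not np.all(np.diff(med) >= -1e-9):
                raise AssertionError("simulated percentile medians not ordered")
        if not ((t["sim_lo"] <= t["sim_median"] + 1e-9)
                & (t["sim_median"] <= t["sim_hi"] + 1e-9)).all():
            raise AssertionError("VPC confidence limits not ordered")

    @property
    def coverage(self) -> float:
        """Fraction of (bin, percentile) cells whose observed percentile lies
        inside the simulated confidence band."""
        t = self.table
        inside = (t["observed"] >= t["sim_lo"]) & (t["observed"] <= t["sim_hi"])
        return float(inside.mean())


def vpc(results: PopPKResults, n_replicates: int = 500, seed: int = 0,
        percentiles=(5.0, 50.0, 95.0), ci: float = 90.0,
        dose_normalize: bool = True, reference_dose: float = 20.0,
        min_bin_count: int = 6) -> VpcSummary:
    """Visual predictive check of a fitted model against its own dataset.

    Observations and simulations are binned by nominal time after dose;
    bins with fewer observations than ``min_bin_count`` are merged into the
    nearest earlier bin. Concentrations below the quantification limit are
    excluded on both the observed and simulated side, mirroring the
    dataset's BLQ handling. Deterministic given ``seed``.
    """
    if n_replicates < 100:
        raise ValueError("VPC needs at least 100 replicates")
    model = results.model
    params = results.params
    b = model._batch
    rng = np.random.default_rng(seed)

    tad, doseamt = _tad_and_dose(model)
    mask = b["obs_mask"]
    scale = (reference_dose / doseamt) if dose_normalize else np.ones_like(doseamt)

    flat_tad = tad[mask]
    # nominal-time bins, merging sparse ones leftward
    uniq = np.unique(np.round(flat_tad, 6))
    counts = {u: int(np.sum(np.round(flat_tad, 6) == u)) for u in uniq}
    bin_of = {}
    current = uniq[0]
    merged_count = 0
    for u in uniq:
        if merged_count < min_bin_count:
            bin_of[u] = current
            merged_count += counts[u]
        else:
            current = u
            bin_of[u] = u
            merged_count = counts[u]
    flat_bins = np.array([bin_of[u] for u in np.round(flat_tad, 6)])
    bins = np.unique(flat_bins)

    def binned_percentiles(dv_flat):
        keep = dv_flat >= LLOQ
        out = np.full((len(bins), len(percentiles)), np.nan)
        for k, tb in enumerate(bins):
            sel = keep & (flat_bins == tb)
            if sel.sum() >= 2:
                out[k] = np.percentile(dv_flat[sel], percentiles)
        return out

    obs = binned_percentiles((b["y"] * scale)[mask])

    sims = np.empty((n_replicates, len(bins), len(percentiles)))
    for r in range(n_replicates):
        dv = model.simulate_observations(params, rng)
        sims[r] = binned_percentiles((dv * scale)[mask])

    lo_q, hi_q = (100.0 - ci) / 2.0, 100.0 - (100.0 - ci) / 2.0
    rows = []
    for k, tb in enumerate(bins):
        for j, pct in enumerate(percentiles):
            col = sims[:, k, j]
            col = col[np.isfinite(col)]
            rows.append({
                "bin_tad": tb, "percentile": pct, "observed": obs[k, j],
                "sim_median": np.median(col),
                "sim_lo": np.percentile(col, lo_q),
                "sim_hi": np.percentile(col, hi_q),
                "n_replicates": len(col)})
    return VpcSummary(pd.DataFrame(rows), n_replicates, seed, ci, dose_normalize)


@dataclass
class BootstrapSummary:
    """Per-parameter bootstrap median and percentile CI over successful
    replicate refits; failures are counted, not silently dropped."""

    table: pd.DataFrame           # index: parameter; median, ci_lo, ci_hi
    n_requested: int
    n_success: int
    seed: int

    def __post_init__(self) -> None:
        t = self.table
        if not ((t["ci_lo"] <= t["median"] + 1e-12)
                & (t["median"] <= t["ci_hi"] + 1e-12)).all():
            raise AssertionError("bootstrap CI not ordered")

    @property
    def n_failed(self) -> int:
        return self.n_requested - self.n_success


def bootstrap(results: PopPKResults, n: int = 1000, seed: int = 0,
              stratify: str | None = "STUDY", ci: float = 95.0,
              maxiter: int = 60) -> BootstrapSummary:
    """Non-parametric bootstrap of a fitted model.

    Subjects are resampled with replacement (within study strata by
    default), each replicate dataset is refitted with the fast preset
    warm-started at the point estimates, and parameter medians with
    percentile confidence intervals are reported. Deterministic per seed.
    """
    if n < 1:
        raise ValueError("bootstrap needs n >= 1")
    model = results.model
    ds = model.dataset
    rng = np.random.default_rng(seed)
    cov = ds.covariate_table()
    strata = ([(s, list(g.index)) for s, g in cov.groupby(stratify, sort=False)]
              if stratify else [("all", ds.subject_ids)])

    estimates = []
    failures = 0
    for _ in range(n):
        ids = []
        for _, members in strata:
            ids.extend(rng.choice(members, size=len(members), replace=True))
        try:
            bds = ds.subset(ids, relabel=True)
            # carry the original covariate references so the covariate model
            # is identical across replicates
            effects = [CovariateEffect(e.parameter, e.covariate, e.form,
                                       model._effect_refs.get(e.name)
                                       if e.form == "continuous" else None)
                       for e in model.covariate_effects]
            bm = PopPKModel(bds, structural=model.structural,
                            covariate_effects=effects, iiv=model.iiv,
                            fixed_omega2=model.fixed_omega2,
                            residual=model.residual)
            fit = bm.fit(start=results.params, preset="fast",
                         maxiter=maxiter, compute_se=False)
            estimates.append(fit.params)
        except Exception:  # noqa: BLE001 - replicate-level failure
            failures += 1
    if not estimates:
        raise RuntimeError("all bootstrap replicates failed")
    if failures > 0.1 * n:
        warnings.warn(f"bootstrap: {failures}/{n} replicates failed")

    frame = pd.DataFrame(estimates)
    lo, hi = (100.0 - ci) / 2.0, 100.0 - (100.0 - ci) / 2.0
    table = pd.DataFrame({
        "median": frame.median(),
        "ci_lo": frame.quantile(lo / 100.0),
        "ci_hi": frame.quantile(hi / 100.0)})
    table.index.name = "parameter"
    return BootstrapSummary(table, n, len(estimates), seed)


# ---------------------------------------------------------------------------
# plotting (artifact output only; not part of the numeric contract)
# ---------------------------------------------------------------------------

def plot_gof(gof: pd.DataFrame, path) -> None:
    """Four-panel GOF figure: DV-PRED, DV-IPRED, CWRES-TAD, CWRES-PRED."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for ax, (x, y) in zip(axes.ravel(),
                          [("PRED", "DV"), ("IPRED", "DV"),
                           ("TAD", "CWRES"), ("PRED", "CWRES")]):
        ax.plot(gof[x], gof[y], ".", ms=3, alpha=0.5)
        if y == "DV":
            lim = [0, max(gof[x].max(), gof[y].max())]
            ax.plot(lim, lim, "k-", lw=0.8)
        else:
            ax.axhline(0, color="k", lw=0.8)
            for yy in (-2, 2):
                ax.axhline(yy, color="r", ls="--", lw=0.8)
        ax.set_xlabel(x)
        ax.set_ylabel(y)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_vpc(summary: VpcSummary, path, log_scale: bool = False) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = summary.table
    fig, ax = plt.subplots(figsize=(8, 5))
    colors = {5.0: "tab:blue", 50.0: "tab:red", 95.0: "tab:blue"}
    for pct, grp in t.groupby("percentile"):
        grp = grp.sort_values("bin_tad")
        c = colors.get(pct, "tab:gray")
        ax.fill_between(grp["bin_tad"], grp["sim_lo"], grp["sim_hi"],
                        alpha=0.25, color=c)
        ax.plot(grp["bin_tad"], grp["sim_median"], "-", color=c, lw=1)
        ax.plot(grp["bin_tad"], grp["observed"], "o--", color=c, ms=4, lw=1)
    ax.set_xlabel("time after dose (h)")
    ax.set_ylabel("concentration (ng/mL)"
                  + (", dose-normalised" if summary.dose_normalized else ""))
    if log_scale:
        ax.set_yscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
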