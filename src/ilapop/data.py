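"""Synthetic population-PK trial data and the long-format dataset container.

The generator emulates the five intravenous-infusion study designs of the
source trials (single-dose crossover 5/10/20 mg, 10 mg q24h multiple dose,
30 mg high dose, 20/10/10 mg loading dose in healthy volunteers, and the
20/10/10 mg duodenal-ulcer study), their printed sampling schedules, the
published baseline covariate distributions, exponential inter-individual
variability, multiplicative residual error, and censoring at the 1 ng/mL
lower limit of quantification.

Datasets use NONMEM-style long format: one row per dose event (``EVID=1``)
or observation (``EVID=0``), comma-delimited with a header. Serum creatinine
is carried in mg/dL (the Cockcroft–Gault unit); the generator converts from
the µmol/L scale of the published baseline table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .covariates import CR_UMOL_PER_MGDL, CovariateRecord, ThetaSet
from .structural import MG_TO_UG, DoseEvent, _conc2_batch

__all__ = [
    "LLOQ",
    "TrialDesign",
    "SimulationTruth",
    "PopPKDataset",
    "builtin_designs",
    "sample_covariates",
    "simulate_trial",
    "build_study_suite",
    "read_dataset",
    "write_dataset",
]

#: lower limit of quantification of the assay, ng/mL
LLOQ = 1.0

REQUIRED_COLUMNS = ["ID", "TIME", "AMT", "DUR", "DV", "EVID", "MDV", "BLQ",
                    "SEX", "DIS", "AGE", "HT", "WT", "SCR"]
LAB_COLUMNS = ["TP", "ALB", "PLT", "ALT", "AST", "TBIL"]

# rich per-day sampling schedule, h after the morning dose
# (15, 30, 45, 50 min then 1–24 h)
_FULL_DAY = (0.0, 0.25, 0.5, 0.75, 50.0 / 60.0, 1.0, 1.5, 2.0, 3.0, 4.0,
             5.0, 8.0, 12.0, 24.0)
# ulcer-study day-1 schedule (25, 45, 55 min then 1.5–24 h)
_ULCER_DAY1 = (0.0, 25.0 / 60.0, 45.0 / 60.0, 55.0 / 60.0, 1.5, 2.0, 3.0,
               5.0, 8.0, 12.0, 24.0)

_INFUSION_H = 0.75


@dataclass(frozen=True)
class TrialDesign:
    """One study arm: dosing events shared by all its subjects and the
    nominal sampling times (absolute hours from the first dose)."""

    label: str
    n_subjects: int
    population: str                      # "healthy" | "ulcer"
    doses: tuple[DoseEvent, ...]
    sampling_times: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.population not in ("healthy", "ulcer"):
            raise ValueError(f"unknown population {self.population!r}")
        t = np.asarray(self.sampling_times)
        if np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be strictly increasing")


def _offsets(day_start: float, offsets) -> list[float]:
    return [day_start + o for o in offsets]


def builtin_designs() -> dict[str, TrialDesign]:
    """The five study arms, n = 16/10/10/12/10 (58 subjects in total).

    The single-dose four-period crossover is emulated as three ilaprazole
    occasions (5, 10, 20 mg) one week apart within each subject.
    """
    designs = {}

    occ = [0.0, 168.0, 336.0]
    t = sorted(set(sum((_offsets(s, _FULL_DAY) for s in occ), [])))
    designs["single_dose"] = TrialDesign(
        "single_dose", 16, "healthy",
        tuple(DoseEvent(a, s, _INFUSION_H) for a, s in zip((5.0, 10.0, 20.0), occ)),
        tuple(t))

    t = sorted(set(_offsets(0.0, _FULL_DAY) + [24.0, 24.75, 72.0, 72.75]
                   + _offsets(96.0, _FULL_DAY)))
    designs["multiple_dose"] = TrialDesign(
        "multiple_dose", 10, "healthy",
        tuple(DoseEvent(10.0, 24.0 * d, _INFUSION_H) for d in range(5)),
        tuple(t))

    designs["high_dose"] = TrialDesign(
        "high_dose", 10, "healthy",
        (DoseEvent(30.0, 0.0, _INFUSION_H),),
        tuple(_offsets(0.0, _FULL_DAY)))

    t = sorted(set(_offsets(0.0, _FULL_DAY) + [24.0, 24.75]
                   + _offsets(48.0, _FULL_DAY)))
    designs["loading_dose"] = TrialDesign(
        "loading_dose", 12, "healthy",
        (DoseEvent(20.0, 0.0, _INFUSION_H),
         DoseEvent(10.0, 24.0, _INFUSION_H),
         DoseEvent(10.0, 48.0, _INFUSION_H)),
        tuple(t))

    t = sorted(set(_offsets(0.0, _ULCER_DAY1) + [24.0, 24.75, 48.0, 48.75]))
    designs["ulcer"] = TrialDesign(
        "ulcer", 10, "ulcer",
        (DoseEvent(20.0, 0.0, _INFUSION_H),
         DoseEvent(10.0, 24.0, _INFUSION_H),
         DoseEvent(10.0, 48.0, _INFUSION_H)),
        tuple(t))
    return designs


@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters: fixed effects plus variance components
    (published final-model estimates by default).

    omega2 holds the inter-individual variances (V, Vp, CL); variability on
    CLp is fixed to zero. sigma_mult is the proportional residual SD."""

    theta: ThetaSet = ThetaSet()
    omega2_V: float = 0.013
    omega2_Vp: float = 0.032
    omega2_CL: float = 0.059
    sigma_mult: float = 0.184

    def __post_init__(self) -> None:
        for name in ("omega2_V", "omega2_Vp", "omega2_CL"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sigma_mult <= 0:
            raise ValueError("sigma_mult must be positive")

    @property
    def omega2(self) -> np.ndarray:
        return np.array([self.omega2_V, self.omega2_Vp, self.omega2_CL])


# ---------------------------------------------------------------------------
# covariate sampling
# ---------------------------------------------------------------------------

# published baseline medians and interquartile ranges; creatinine in µmol/L
_COV_MARGINALS = {
    "healthy": {
        "AGE": (25.0, 23.0, 31.0), "HT": (168.0, 160.5, 172.3),
        "WT": (60.6, 55.8, 65.1), "TP": (72.8, 70.7, 75.7),
        "ALB": (45.4, 43.6, 47.5), "PLT": (220.0, 196.0, 262.3),
        "ALT": (14.1, 9.8, 19.2), "AST": (17.9, 15.2, 21.6),
        "TBIL": (11.6, 8.2, 13.6), "CR": (67.4, 58.5, 79.6),
    },
    "ulcer": {
        "AGE": (46.0, 38.3, 50.5), "HT": (168.5, 159.8, 170.0),
        "WT": (63.0, 58.8, 65.0), "TP": (71.2, 70.5, 73.2),
        "ALB": (45.3, 43.2, 47.6), "PLT": (222.0, 185.5, 254.3),
        "ALT": (19.6, 15.6, 27.0), "AST": (22.6, 17.6, 25.7),
        "TBIL": (12.4, 9.1, 16.2), "CR": (72.5, 57.1, 82.7),
    },
}
_COV_ORDER = list(_COV_MARGINALS["healthy"])

# Gaussian-copula correlations chosen so squared sample correlations land
# near the published collinearity findings (r² ≈ 0.81 WT–HT, 0.64 TP–ALB,
# 0.77 AST–ALT)
_COPULA_PAIRS = {("WT", "HT"): 0.90, ("TP", "ALB"): 0.80, ("AST", "ALT"): 0.876}

_P_FEMALE = {"healthy": 0.5, "ulcer": 0.4}
_NORM_IQR = 1.3489795003921634  # Phi^-1(0.75) - Phi^-1(0.25)


def sample_covariates(n: int, population: str = "healthy",
                      seed: int | np.random.Generator = 0) -> list[CovariateRecord]:
    """Draw ``n`` baseline covariate records for one population.

    Marginals are log-normal matched to the published medians and IQRs; the
    collinear pairs (weight–height, total protein–albumin, AST–ALT) are
    coupled through a Gaussian copula. Sex is assigned by an exact-count
    shuffle (50% female in healthy arms, 40% in the ulcer arm), matching the
    published per-study counts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if population not in _COV_MARGINALS:
        raise ValueError(f"unknown population {population!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    k = len(_COV_ORDER)
    corr = np.eye(k)
    for (a, b), r in _COPULA_PAIRS.items():
        ia, ib = _COV_ORDER.index(a), _COV_ORDER.index(b)
        corr[ia, ib] = corr[ib, ia] = r
    z = rng.multivariate_normal(np.zeros(k), corr, size=n, method="cholesky")

    draws = {}
    for j, name in enumerate(_COV_ORDER):
        med, q1, q3 = _COV_MARGINALS[population][name]
        mu = np.log(med)
        sigma = (np.log(q3) - np.log(q1)) / _NORM_IQR
        draws[name] = np.exp(mu + sigma * z[:, j])

    n_female = int(round(n * _P_FEMALE[population]))
    sex = np.array([1] * n_female + [0] * (n - n_female))
    rng.shuffle(sex)

    disease = 1 if population == "ulcer" else 0
    records = []
    for i in range(n):
        records.append(CovariateRecord(
            sex=int(sex[i]), disease=disease, age=float(draws["AGE"][i]),
            height=float(draws["HT"][i]), weight=float(draws["WT"][i]),
            serum_creatinine=float(draws["CR"][i] / CR_UMOL_PER_MGDL),
            TP=float(draws["TP"][i]), ALB=float(draws["ALB"][i]),
            PLT=float(draws["PLT"][i]), ALT=float(draws["ALT"][i]),
            AST=float(draws["AST"][i]), TBIL=float(draws["TBIL"][i])))
    return records


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

class PopPKDataset:
    """Long-format dosing + observation table for many subjects.

    Wraps a validated :class:`pandas.DataFrame`. Rows with ``EVID=1`` are
    dose events (``AMT`` mg over ``DUR`` h); rows with ``EVID=0`` are
    observations (``DV`` ng/mL). ``BLQ=1`` marks concentrations below the
    1 ng/mL quantification limit — they are kept in the table but excluded
    from the likelihood (``MDV=1``).
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset is missing mandatory columns: {missing}")
        df = frame.copy().reset_index(drop=True)
        if "STUDY" not in df.columns:
            df["STUDY"] = "study1"
        for sid, grp in df.groupby("ID", sort=False):
            times = grp["TIME"].to_numpy(float)
            if np.any(np.diff(times) < 0):
                raise ValueError(f"subject {sid}: times are not non-decreasing")
            doses = grp[grp["EVID"] == 1]
            obs = grp[grp["EVID"] == 0]
            if len(doses) == 0:
                raise ValueError(f"subject {sid}: no dose events")
            if len(obs) and obs["TIME"].min() < doses["TIME"].min():
                raise ValueError(
                    f"subject {sid}: observation precedes every dose event")
        self.frame = df

    # -- basic accessors ----------------------------------------------------
    @property
    def subject_ids(self) -> list:
        return list(dict.fromkeys(self.frame["ID"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_obs(self) -> int:
        """Number of observations entering the likelihood (non-BLQ)."""
        f = self.frame
        return int(((f["EVID"] == 0) & (f["MDV"] == 0)).sum())

    def covariate_table(self) -> pd.DataFrame:
        """One row per subject with the baseline covariates."""
        cols = ["SEX", "DIS", "AGE", "HT", "WT", "SCR"] + \
            [c for c in LAB_COLUMNS if c in self.frame.columns] + ["STUDY"]
        return (self.frame.groupby("ID", sort=False)[cols].first())

    def subset(self, ids, relabel: bool = False) -> "PopPKDataset":
        """Rows of the listed subjects; with ``relabel`` they get fresh IDs
        (needed when bootstrap resampling duplicates a subject)."""
        parts = []
        for new, sid in enumerate(ids, start=1):
            g = self.frame[self.frame["ID"] == sid].copy()
            if relabel:
                g["ID"] = new
            parts.append(g)
        return PopPKDataset(pd.concat(parts, ignore_index=True))

    # -- padded arrays for the vectorised engine ----------------------------
    def padded_arrays(self) -> dict:
        """Ragged per-subject data padded to rectangular masked arrays."""
        ids = self.subject_ids
        obs_t, obs_y, dose = [], [], []
        for sid in ids:
            g = self.frame[self.frame["ID"] == sid]
            o = g[(g["EVID"] == 0) & (g["MDV"] == 0)]
            obs_t.append(o["TIME"].to_numpy(float))
            obs_y.append(o["DV"].to_numpy(float))
            d = g[g["EVID"] == 1]
            dose.append((d["AMT"].to_numpy(float) * MG_TO_UG,
                         d["TIME"].to_numpy(float),
                         d["DUR"].to_numpy(float)))
        N = len(ids)
        T = max(len(t) for t in obs_t)
        D = max(len(d[0]) for d in dose)
        out = dict(
            ids=ids,
            times=np.zeros((N, T)), y=np.ones((N, T)), obs_mask=np.zeros((N, T), bool),
            amt=np.zeros((N, D)), start=np.zeros((N, D)),
            dur=np.ones((N, D)), dose_mask=np.zeros((N, D), bool))
        for i, (t, y, (a, s, d)) in enumerate(zip(obs_t, obs_y, dose)):
            out["times"][i, :len(t)] = t
            out["y"][i, :len(t)] = y
            out["obs_mask"][i, :len(t)] = True
            out["amt"][i, :len(a)] = a
            out["start"][i, :len(a)] = s
            out["dur"][i, :len(a)] = d
            out["dose_mask"][i, :len(a)] = True
        return out


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _individual_param_arrays(truth: SimulationTruth, covs, eta: np.ndarray):
    """Vectorised final-model parameters for a list of covariate records."""
    th = truth.theta
    sex = np.array([c.sex for c in covs], float)
    dis = np.array([c.disease for c in covs], float)
    wt = np.array([c.weight for c in covs], float)
    V = th.tv_V * np.exp(eta[:, 0])
    Vp = (th.tv_Vp * (wt / th.wt_reference) ** th.theta_wt_Vp
          * np.exp(th.theta_dis_Vp * dis) * np.exp(eta[:, 1]))
    CL = (th.tv_CL * np.exp(th.theta_sex_CL * sex)
          * np.exp(th.theta_dis_CL * dis) * np.exp(eta[:, 2]))
    CLp = np.full_like(V, th.tv_CLp)
    return V, Vp, CL, CLp


def simulate_trial(design: TrialDesign, truth: SimulationTruth = SimulationTruth(),
                   seed: int | np.random.Generator = 0,
                   id_offset: int = 0, dropout: float = 0.0) -> PopPKDataset:
    """Simulate one study arm under the final model.

    Per subject: covariates from the published baseline distributions,
    ``eta ~ N(0, diag(omega2))``, individual parameters by the covariate
    model, concentrations from the two-compartment closed form, then
    multiplicative noise ``DV = f * (1 + eps)``. Values below 1 ng/mL
    (including all pre-dose samples) are flagged BLQ and excluded from the
    likelihood. ``dropout`` randomly blanks that fraction of observations
    (missed samples), default off.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = design.n_subjects
    covs = [replace(c, age=round(c.age, 1), height=round(c.height, 1),
                    weight=round(c.weight, 1),
                    serum_creatinine=round(c.serum_creatinine, 4),
                    TP=round(c.TP, 1), ALB=round(c.ALB, 1),
                    PLT=round(c.PLT, 0), ALT=round(c.ALT, 1),
                    AST=round(c.AST, 1), TBIL=round(c.TBIL, 1))
            for c in sample_covariates(n, design.population, rng)]
    eta = rng.normal(0.0, np.sqrt(truth.omega2), size=(n, 3))
    V, Vp, CL, CLp = _individual_param_arrays(truth, covs, eta)

    t = np.asarray(design.sampling_times, float)
    amt = np.array([[e.amount * MG_TO_UG for e in design.doses]])
    start = np.array([[e.start_time for e in design.doses]])
    dur = np.array([[e.duration for e in design.doses]])
    mask = np.ones_like(amt, bool)
    f = _conc2_batch(V, Vp, CL, CLp, np.broadcast_to(t, (n, t.size)),
                     amt, start, dur, mask)
    eps = rng.normal(0.0, truth.sigma_mult, size=f.shape)
    dv = np.maximum(f * (1.0 + eps), 0.0)

    drop = (rng.random(f.shape) < dropout) if dropout > 0 else np.zeros(f.shape, bool)

    rows = []
    for i in range(n):
        sid = id_offset + i + 1
        c = covs[i]
        base = dict(ID=sid, STUDY=design.label, SEX=c.sex, DIS=c.disease,
                    AGE=round(c.age, 1), HT=round(c.height, 1),
                    WT=round(c.weight, 1), SCR=round(c.serum_creatinine, 4),
                    TP=round(c.TP, 1), ALB=round(c.ALB, 1), PLT=round(c.PLT, 0),
                    ALT=round(c.ALT, 1), AST=round(c.AST, 1), TBIL=round(c.TBIL, 1))
        for e in design.doses:
            rows.append(dict(base, TIME=e.start_time, AMT=e.amount,
                             DUR=e.duration, DV=0.0, EVID=1, MDV=1, BLQ=0))
        for j, tj in enumerate(t):
            if drop[i, j]:
                continue
            blq = int(dv[i, j] < LLOQ)
            rows.append(dict(base, TIME=tj, AMT=0.0, DUR=0.0,
                             DV=float(dv[i, j]), EVID=0, MDV=blq, BLQ=blq))
    df = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"],
                                        ascending=[True, True, False])
    cols = ["ID", "STUDY", "TIME", "AMT", "DUR", "DV", "EVID", "MDV", "BLQ",
            "SEX", "DIS", "AGE", "HT", "WT", "SCR"] + LAB_COLUMNS
    return PopPKDataset(df[cols])


def build_study_suite(truth: SimulationTruth = SimulationTruth(),
                      seed: int = 0, dropout: float = 0.0) -> PopPKDataset:
    """The full 58-subject synthetic study pool: all five arms concatenated
    with a ``STUDY`` label and globally unique subject IDs."""
    rng = np.random.default_rng(seed)
    parts, offset = [], 0
    for design in builtin_designs().values():
        ds = simulate_trial(design, truth, rng, id_offset=offset, dropout=dropout)
        offset += design.n_subjects
        parts.append(ds.frame)
    return PopPKDataset(pd.concat(parts, ignore_index=True))


# ---------------------------------------------------------------------------
# delimited I/O
# ---------------------------------------------------------------------------

def write_dataset(dataset: PopPKDataset, path) -> None:
    dataset.frame.to_csv(path, index=False)


def read_dataset(path) -> PopPKDataset:
    df = pd.read_csv(path)
    return PopPKDataset(df)
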