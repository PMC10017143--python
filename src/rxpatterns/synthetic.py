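"""Synthetic linked GP-extract generator with planted latent co-prescription structure.

Emulates the shape of a primary-care dementia cohort: one index (diagnosis)
date per patient, medication events scattered over the 20 years before it,
and a linked diagnosis-event table sharing the patient identifier.
Co-prescription is generated from a latent factor model: per period, factor
scores f ~ N(0, Phi), latent responses y = Lambda f + sqrt(psi) * e, and a
medication is prescribed iff its latent response exceeds a threshold chosen
to hit a target marginal prescription prevalence.  The threshold (probit)
construction makes tetrachoric correlations of the binary indicators exactly
model-consistent, so factor-recovery tests are well posed.

Diagnosis events are planted per cluster: patients belonging to a factor
(by the same >=3-salient-drugs rule used downstream) receive each linked
diagnosis code with a planned prevalence, which gives every descriptive
table a known truth to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .utils import YEAR_DAYS, InvalidSpecError, child_rng
from .windows import DEFAULT_WINDOWS, PeriodWindow, windows_from_pairs

#: 3-character disease chapters used for fixture realism (UK primary-care style).
DISEASE_CODES = ("H06", "N24", "R00", "N05", "N09", "N14", "K19", "G20", "N33")


@dataclass
class CohortSpec:
    """Cohort-level simulation parameters.

    Defaults mirror the study population the generator emulates: 65.8%
    female, mean diagnosis age 82.2 (female) / 66.2 (male) years, a 20-year
    observation span split into four 5-year windows, and a majority of
    patients contributing less than the full 20 years of history (which
    yields the monotone shrinking per-period cohorts seen in registry data).
    """

    n_patients: int
    female_fraction: float = 0.658
    diagnosis_age_mean_female: float = 82.2
    diagnosis_age_mean_male: float = 66.2
    diagnosis_age_sd: float = 6.0
    observation_span: float = 20.0
    periods: tuple = ((0, 5), (5, 10), (10, 15), (15, 20))
    full_history_fraction: float = 0.15
    index_date_start: str = "2005-01-01"
    index_date_end: str = "2015-01-01"
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise InvalidSpecError(f"n_patients must be >= 1, got {self.n_patients}")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise InvalidSpecError("female_fraction must lie in [0, 1]")
        wins = self.windows()
        if not np.isclose(wins[0].lower_years, 0.0) or not np.isclose(
            wins[-1].upper_years, self.observation_span
        ):
            raise InvalidSpecError("period windows must cover (0, observation_span]")

    def windows(self) -> tuple[PeriodWindow, ...]:
        return windows_from_pairs(self.periods)


@dataclass
class PlantedFactorSpec:
    """The latent factor model planted in one period.

    ``loadings`` is the p x F pattern matrix Lambda, ``factor_correlations``
    the F x F matrix Phi, and ``marginal_prevalence`` the target per-
    medication prescription probability (which fixes the probit threshold,
    since each latent response has unit variance).
    """

    period_index: int
    medication_codes: list
    loadings: np.ndarray
    factor_correlations: np.ndarray
    marginal_prevalence: np.ndarray
    noise_loading_cap: float = 0.1

    def __post_init__(self):
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.factor_correlations = np.asarray(self.factor_correlations, dtype=float)
        self.marginal_prevalence = np.broadcast_to(
            np.asarray(self.marginal_prevalence, dtype=float), (self.loadings.shape[0],)
        ).copy()
        p, F = self.loadings.shape
        if len(self.medication_codes) != p:
            raise InvalidSpecError("medication_codes length must match loading rows")
        if not np.allclose(self.factor_correlations, self.factor_correlations.T):
            raise InvalidSpecError("factor_correlations must be symmetric")
        try:
            np.linalg.cholesky(self.factor_correlations)
        except np.linalg.LinAlgError as exc:
            raise InvalidSpecError("factor_correlations must be positive definite") from exc
        if np.any(self.uniquenesses < -1e-10):
            raise InvalidSpecError(
                "implied correlation has communalities > 1; shrink the loadings"
            )
        if np.any((self.marginal_prevalence <= 0) | (self.marginal_prevalence >= 1)):
            raise InvalidSpecError("marginal_prevalence must lie strictly in (0, 1)")
        salient = (np.abs(self.loadings) > 0.30).sum(axis=0)
        if np.any(salient > 0) and np.any(salient[salient > 0] < 3):
            raise InvalidSpecError(
                "every non-null factor needs >= 3 salient (|loading| > 0.30) medications"
            )

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def communalities(self) -> np.ndarray:
        return np.diag(self.loadings @ self.factor_correlations @ self.loadings.T)

    @property
    def uniquenesses(self) -> np.ndarray:
        return 1.0 - self.communalities

    @property
    def thresholds(self) -> np.ndarray:
        """Probit thresholds implied by the target marginal prevalences."""
        return stats.norm.ppf(1.0 - self.marginal_prevalence)

    def implied_correlation(self) -> np.ndarray:
        """Latent-scale correlation Lambda Phi Lambda' + Psi (unit diagonal)."""
        sigma = self.loadings @ self.factor_correlations @ self.loadings.T
        np.fill_diagonal(sigma, 1.0)
        return sigma

    def salient_sets(self, threshold: float = 0.30) -> dict[int, list]:
        codes = np.asarray(self.medication_codes)
        return {
            k + 1: list(codes[np.abs(self.loadings[:, k]) > threshold])
            for k in range(self.n_factors)
        }


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated dataset: planted models plus, after
    generation, the realised presence matrices, factor scores and cluster
    memberships (all keyed by period index)."""

    factor_specs: dict[int, PlantedFactorSpec]
    disease_prevalence: dict[int, dict[int, dict[str, float]]]
    true_scores: dict[int, pd.DataFrame] = field(default_factory=dict)
    presence: dict[int, pd.DataFrame] = field(default_factory=dict)
    memberships: dict[int, dict[int, set]] = field(default_factory=dict)

    def __post_init__(self):
        for period, per_factor in self.disease_prevalence.items():
            for factor, codes in per_factor.items():
                if not codes:
                    raise InvalidSpecError(
                        f"period {period} factor {factor}: every factor needs >= 1 diagnosis code"
                    )
                for code, q in codes.items():
                    if not 0.0 <= q <= 1.0:
                        raise InvalidSpecError(
                            f"planned prevalence for {code} must lie in [0, 1], got {q}"
                        )

    def to_json(self, path) -> None:
        payload = {
            "factor_specs": {
                str(k): {
                    "period_index": s.period_index,
                    "medication_codes": list(s.medication_codes),
                    "loadings": s.loadings.tolist(),
                    "factor_correlations": s.factor_correlations.tolist(),
                    "marginal_prevalence": s.marginal_prevalence.tolist(),
                    "noise_loading_cap": s.noise_loading_cap,
                }
                for k, s in self.factor_specs.items()
            },
            "disease_prevalence": {
                str(p): {str(f): dict(codes) for f, codes in per.items()}
                for p, per in self.disease_prevalence.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        specs = {
            int(k): PlantedFactorSpec(
                period_index=v["period_index"],
                medication_codes=v["medication_codes"],
                loadings=np.array(v["loadings"]),
                factor_correlations=np.array(v["factor_correlations"]),
                marginal_prevalence=np.array(v["marginal_prevalence"]),
                noise_loading_cap=v["noise_loading_cap"],
            )
            for k, v in payload["factor_specs"].items()
        }
        prev = {
            int(p): {int(f): dict(codes) for f, codes in per.items()}
            for p, per in payload["disease_prevalence"].items()
        }
        return cls(factor_specs=specs, disease_prevalence=prev)


def block_loadings(
    n_factors: int = 3,
    meds_per_factor: int = 10,
    salient: float = 0.8,
    phi_offdiag: float = 0.3,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Simple-structure loading blocks: each factor owns ``meds_per_factor``
    medications at |loading| = salient, zeros elsewhere."""
    p = n_factors * meds_per_factor
    lam = np.zeros((p, n_factors))
    for k in range(n_factors):
        lam[k * meds_per_factor : (k + 1) * meds_per_factor, k] = salient
    phi = np.full((n_factors, n_factors), phi_offdiag)
    np.fill_diagonal(phi, 1.0)
    codes = [f"M{j + 1:03d}" for j in range(p)]
    return lam, phi, codes


#: Planned per-cluster disease prevalences used by the default truth;
#: magnitudes follow the descriptive tables the generator emulates.
_DEFAULT_DISEASE_PREVALENCE = {
    1: {
        "H06": 0.2665, "N24": 0.2514, "R00": 0.2168, "N05": 0.1610,
        "N09": 0.1531, "N14": 0.1453, "K19": 0.1429, "G20": 0.1321,
    },
    2: {
        "H06": 0.2782, "N24": 0.2601, "R00": 0.2204, "N05": 0.1644,
        "N09": 0.1577, "K19": 0.1507, "N14": 0.1480, "G20": 0.1335,
    },
    3: {
        "N24": 0.4059, "N33": 0.3904, "H06": 0.3904, "N09": 0.2921,
        "R00": 0.2837, "N14": 0.2700, "N05": 0.2289, "K19": 0.2092,
    },
}


def default_truth(
    spec: CohortSpec,
    n_factors: int = 3,
    meds_per_factor: int = 10,
    salient: float = 0.8,
    phi_offdiag: float = 0.3,
    marginal_prevalence: float = 0.15,
) -> SyntheticTruth:
    """Plant the same simple oblique structure in every period, with the
    default cluster-disease prevalence map."""
    lam, phi, codes = block_loadings(n_factors, meds_per_factor, salient, phi_offdiag)
    specs = {
        w.index: PlantedFactorSpec(
            period_index=w.index,
            medication_codes=codes,
            loadings=lam,
            factor_correlations=phi,
            marginal_prevalence=np.full(len(codes), marginal_prevalence),
        )
        for w in spec.windows()
    }
    dx = {
        w.index: {
            k: dict(_DEFAULT_DISEASE_PREVALENCE[min(k, 3)]) for k in range(1, n_factors + 1)
        }
        for w in spec.windows()
    }
    return SyntheticTruth(factor_specs=specs, disease_prevalence=dx)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Patient table: id, gender, date of birth, diagnosis date, history span.

    Diagnosis age is Gaussian per gender; the index date is uniform over the
    configured calendar range; ``history_years`` is the length of GP history
    available before the index date (full span with probability
    ``full_history_fraction``, otherwise uniform on (0, span)), which is what
    makes later periods cover fewer patients.
    """
    rng = child_rng(spec.seed, 0)
    n = spec.n_patients
    ids = [f"P{i + 1:06d}" for i in range(n)]
    female = rng.random(n) < spec.female_fraction
    age_mean = np.where(female, spec.diagnosis_age_mean_female, spec.diagnosis_age_mean_male)
    age = rng.normal(age_mean, spec.diagnosis_age_sd).clip(40.0, 105.0)
    start = pd.Timestamp(spec.index_date_start)
    span_days = (pd.Timestamp(spec.index_date_end) - start).days
    dx_date = start + pd.to_timedelta(rng.integers(0, max(span_days, 1), n), unit="D")
    dob = dx_date - pd.to_timedelta(np.round(age * YEAR_DAYS).astype(int), unit="D")
    full = rng.random(n) < spec.full_history_fraction
    history = np.where(full, spec.observation_span, rng.uniform(0.0, spec.observation_span, n))
    return pd.DataFrame(
        {
            "patient_id": ids,
            "gender": np.where(female, "F", "M"),
            "date_of_birth": dob,
            "diagnosis_date": dx_date,
            "history_years": history,
        }
    )


def _event_days(u_years: np.ndarray, window: PeriodWindow) -> np.ndarray:
    """Convert year offsets to integer day offsets that stay inside the
    window under 365.25-day arithmetic and strictly before the index date."""
    lo = max(1, int(np.ceil(window.lower_years * YEAR_DAYS)))
    hi = int(np.ceil(window.upper_years * YEAR_DAYS)) - 1
    return np.clip(np.floor(u_years * YEAR_DAYS).astype(int), lo, hi)


def sample_indicator_matrix(
    fs: PlantedFactorSpec, n_patients: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (presence, factor scores) for n patients under the planted model."""
    chol = np.linalg.cholesky(fs.factor_correlations)
    scores = rng.standard_normal((n_patients, fs.n_factors)) @ chol.T
    psi = np.sqrt(np.clip(fs.uniquenesses, 0.0, None))
    latent = scores @ fs.loadings.T + rng.standard_normal((n_patients, len(fs.medication_codes))) * psi
    return latent > fs.thresholds, scores


def generate_medication_events(
    patients: pd.DataFrame, truth: SyntheticTruth, spec: CohortSpec
) -> pd.DataFrame:
    """Materialise dated medication events from the planted factor model.

    Per period: draw factor scores ~ N(0, Phi), form latent responses,
    threshold to a presence matrix, then emit 1 + Poisson(2) dated events
    per prescribed (patient, medication), uniformly inside the window and
    truncated to each patient's available history.  Fills ``truth``'s
    presence / true-score / membership slots as a side effect.
    """
    windows = {w.index: w for w in spec.windows()}
    frames = []
    for k, fs in sorted(truth.factor_specs.items()):
        win = windows[k]
        rng = child_rng(spec.seed, 10, k)
        # patients whose history reaches into this window
        live = patients[patients["history_years"] > win.lower_years].reset_index(drop=True)
        presence, scores = sample_indicator_matrix(fs, len(live), rng)
        truth.true_scores[k] = pd.DataFrame(
            scores, index=live["patient_id"], columns=[f"F{j + 1}" for j in range(fs.n_factors)]
        )
        pres_df = pd.DataFrame(presence, index=live["patient_id"], columns=fs.medication_codes)
        truth.presence[k] = pres_df
        truth.memberships[k] = planted_membership(fs, pres_df)

        rows, cols = np.nonzero(presence)
        if len(rows) == 0:
            continue
        reps = 1 + rng.poisson(2.0, size=len(rows))
        rows_r = np.repeat(rows, reps)
        cols_r = np.repeat(cols, reps)
        hi_eff = np.minimum(win.upper_years, live["history_years"].to_numpy())[rows_r]
        u = rng.uniform(win.lower_years, hi_eff)
        days = _event_days(u, win)
        dx = live["diagnosis_date"].to_numpy()[rows_r]
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": live["patient_id"].to_numpy()[rows_r],
                    "event_date": pd.to_datetime(dx) - pd.to_timedelta(days, unit="D"),
                    "medication_code": np.asarray(fs.medication_codes)[cols_r],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["patient_id", "event_date", "medication_code"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["patient_id", "event_date", "medication_code"]).reset_index(drop=True)


def planted_membership(
    fs: PlantedFactorSpec,
    presence: pd.DataFrame,
    min_drugs: int = 3,
    threshold: float = 0.30,
) -> dict[int, set]:
    """Ground-truth cluster membership: the >=min_drugs-salient-medications
    rule applied to the planted salient sets and the realised presence."""
    out = {}
    for f, codes in fs.salient_sets(threshold).items():
        if not codes:
            out[f] = set()
            continue
        hits = presence[codes].to_numpy().sum(axis=1)
        out[f] = set(presence.index[hits >= min_drugs])
    return out


def generate_diagnosis_events(
    patients: pd.DataFrame,
    truth: SyntheticTruth,
    membership: dict[int, dict[int, set]],
    spec: CohortSpec,
    background_prevalence: float = 0.0,
) -> pd.DataFrame:
    """Plant diagnosis events: each cluster member receives each linked code
    with its planned prevalence (>=1 dated event inside the window); non-
    members receive codes at ``background_prevalence``."""
    if not 0.0 <= background_prevalence <= 1.0:
        raise InvalidSpecError("background_prevalence must lie in [0, 1]")
    windows = {w.index: w for w in spec.windows()}
    pat = patients.set_index("patient_id")
    frames = []
    for k, per_factor in sorted(truth.disease_prevalence.items()):
        win = windows[k]
        rng = child_rng(spec.seed, 20, k)
        live = patients[patients["history_years"] > win.lower_years]
        live_ids = live["patient_id"].to_numpy()
        for f in sorted(per_factor):
            members = np.array(sorted(membership.get(k, {}).get(f, set())), dtype=object)
            for code in sorted(per_factor[f]):
                q = per_factor[f][code]
                hit = members[rng.random(len(members)) < q] if len(members) else members
                if background_prevalence > 0:
                    nonmembers = np.setdiff1d(live_ids, members)
                    bg = nonmembers[rng.random(len(nonmembers)) < background_prevalence]
                    hit = np.concatenate([hit, bg])
                if len(hit) == 0:
                    continue
                hist = pat.loc[hit, "history_years"].to_numpy()
                u = rng.uniform(win.lower_years, np.minimum(win.upper_years, hist))
                days = _event_days(u, win)
                dx = pd.to_datetime(pat.loc[hit, "diagnosis_date"].to_numpy())
                frames.append(
                    pd.DataFrame(
                        {
                            "patient_id": hit,
                            "event_date": dx - pd.to_timedelta(days, unit="D"),
                            "diagnosis_code": code,
                        }
                    )
                )
    if not frames:
        return pd.DataFrame(columns=["patient_id", "event_date", "diagnosis_code"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["patient_id", "event_date", "diagnosis_code"]).reset_index(drop=True)


@dataclass
class SyntheticDataset:
    """One fully generated linked extract plus its ground truth."""

    spec: CohortSpec
    truth: SyntheticTruth
    patients: pd.DataFrame
    med_events: pd.DataFrame
    dx_events: pd.DataFrame


def generate_dataset(spec: CohortSpec, truth: SyntheticTruth | None = None) -> SyntheticDataset:
    """Convenience end-to-end generation with the default planted structure."""
    if truth is None:
        truth = default_truth(spec)
    patients = generate_cohort(spec)
    med_events = generate_medication_events(patients, truth, spec)
    dx_events = generate_diagnosis_events(patients, truth, truth.memberships, spec)
    return SyntheticDataset(spec, truth, patients, med_events, dx_events)


def write_dataset(ds: SyntheticDataset, out_dir) -> None:
    """Write patients.csv / med_events.csv / dx_events.csv / truth.json."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pat = ds.patients.copy()
    for col in ("date_of_birth", "diagnosis_date"):
        pat[col] = pd.to_datetime(pat[col]).dt.strftime("%Y-%m-%d")
    pat.to_csv(out / "patients.csv", index=False)
    for name, df, datecol in (
        ("med_events.csv", ds.med_events, "event_date"),
        ("dx_events.csv", ds.dx_events, "event_date"),
    ):
        d = df.copy()
        d[datecol] = pd.to_datetime(d[datecol]).dt.strftime("%Y-%m-%d")
        d.to_csv(out / name, index=False)
    ds.truth.to_json(out / "truth.json")


def read_dataset(in_dir) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read the three CSVs back (dates parsed); truth.json is read separately."""
    from pathlib import Path

    p = Path(in_dir)
    patients = pd.read_csv(p / "patients.csv", comment="#")
    patients["date_of_birth"] = pd.to_datetime(patients["date_of_birth"])
    patients["diagnosis_date"] = pd.to_datetime(patients["diagnosis_date"])
    med = pd.read_csv(p / "med_events.csv", comment="#")
    med["event_date"] = pd.to_datetime(med["event_date"])
    dx = pd.read_csv(p / "dx_events.csv", comment="#")
    dx["event_date"] = pd.to_datetime(dx["event_date"])
    return patients, med, dx
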