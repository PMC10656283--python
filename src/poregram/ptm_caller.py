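"""Locating and classifying post-translational modifications within events.

A modified Trx-linker unit shows a deeper A1 blockade (smaller I_res%) and
elevated rms noise than the unmodified units of the same polypeptide. The
caller finds it with a leave-one-out outlier test on the within-event A1
residual currents: for each feature, z = (median of the others - own) /
(robust spread of the others, floored at the measurement error); the
maximum-z feature is called modified when z exceeds a threshold (default
3) and its blockade is deeper than the rest. The reported dIres% keeps its
mean-based definition. Species are then assigned by maximum likelihood under per-species 2-D
Gaussians in the (dIres%, corrected rms) plane, with an explicit ambiguous
outcome when the top two likelihoods are close — overlapping species clouds
are a real feature of the data, not an error.

Threading order convention: for C-first events feature 1 is the
C-terminal-most unit; for N-first events the order is reversed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .levelstats import a1_table

Z_MIN_DEFAULT = 3.0
AMBIGUITY_RATIO = 3.0  # top-two likelihood ratio below this -> ambiguous


@dataclass
class PTMCall:
    event_id: int
    modified_feature_idx: int | None  # 1-based in threading order; None = no call
    delta_ires: float | None  # percentage points
    rms_corr: float | None  # pA, corrected rms of the called A1
    species_call: str  # "P" | "GSH" | "SLN" | ... | "none" | "ambiguous"
    score: float  # leave-one-out z of the called (or best) feature
    multi_candidate: bool = False


def _robust_sd(x: np.ndarray) -> float:
    mad = np.median(np.abs(x - np.median(x)))
    if mad > 0:
        return float(1.482602218505602 * mad)
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def loo_z_scores(a1_ires: np.ndarray, sem: np.ndarray | None = None) -> np.ndarray:
    """Leave-one-out outlier z for each feature's A1 residual current.

    Positive z means the feature blocks more current (lower I_res%) than
    the median of the remaining features. When per-level standard errors
    are given, each z is scaled by ``sqrt(sd_others^2 + sem_i^2)`` — the
    A1 means of short levels carry more sampling error than the
    between-unit spread, and ignoring that fakes outliers.
    """
    n = a1_ires.size
    z = np.empty(n)
    for i in range(n):
        others = np.delete(a1_ires, i)
        var = _robust_sd(others) ** 2
        if sem is not None:
            # the between-unit spread cannot be below the per-level
            # measurement error; flooring guards the noisy small-n MAD
            sem_o = np.delete(sem, i)
            var = max(var, float(np.median(sem_o)) ** 2) + sem[i] ** 2
        # median reference: a single anomalous unit in "others" must not
        # drag the mean and fake outliers everywhere else
        z[i] = (np.median(others) - a1_ires[i]) / np.sqrt(var) if var > 0 else 0.0
    return z


MIN_A1_DWELL_MS = 1.0  # caller quality filter: shorter A1 means are smear-biased


def locate_modified_unit(
    stats: pd.DataFrame,
    event_id: int,
    z_min: float = Z_MIN_DEFAULT,
    min_dwell_ms: float = MIN_A1_DWELL_MS,
) -> PTMCall:
    """Locate the modified unit of one event, or call none.

    Requires at least three features with usable (unexcluded) A1 levels.
    A1 levels shorter than ``min_dwell_ms`` are not candidates and do not
    enter the reference mean: a mean over a handful of filtered samples is
    biased toward the neighbouring levels and would fake an outlier. When
    more than one feature clears ``z_min`` the highest-z one is called and
    the event is flagged multi-candidate.
    """
    a1 = a1_table(stats, event_id)
    a1 = a1[a1.dwell_ms >= min_dwell_ms]
    if len(a1) < 3:
        raise ValueError("event needs >= 3 usable A1 levels for localization")
    ires = a1.ires_pct.to_numpy()
    sem = a1.sem_ires.to_numpy() if "sem_ires" in a1.columns else None
    z = loo_z_scores(ires, sem)
    best = int(np.argmax(z))
    n_hits = int((z > z_min).sum())
    if z[best] > z_min:  # z > 0 already implies a deeper blockade than the rest
        row = a1.iloc[best]
        others = np.delete(ires, best)
        return PTMCall(
            event_id=event_id,
            modified_feature_idx=int(row.feature_idx),
            delta_ires=float(others.mean() - ires[best]),
            rms_corr=float(row.rms_corr_pA),
            species_call="uncalled",
            score=float(z[best]),
            multi_candidate=n_hits > 1,
        )
    return PTMCall(event_id, None, None, None, "none", float(z[best]))


# ---------------------------------------------------------------------------
# species classification


@dataclass
class ClassModel:
    """Per-species 2-D Gaussians in the (dIres%, corrected rms) plane."""

    species: list
    means: dict  # species -> (2,) array
    covs: dict  # species -> (2, 2) array
    masses: dict  # species -> Da

    @classmethod
    def fit(cls, points: pd.DataFrame, masses: dict) -> "ClassModel":
        """Fit from labelled calibration events.

        ``points`` needs columns (species, delta_ires, rms_corr); each
        species needs >= 3 events for a non-degenerate covariance.
        """
        species, means, covs = [], {}, {}
        for sp, grp in points.groupby("species", sort=True):
            xy = grp[["delta_ires", "rms_corr"]].to_numpy()
            if len(xy) < 3:
                raise ValueError(f"species {sp!r}: need >= 3 calibration events")
            species.append(sp)
            means[sp] = xy.mean(axis=0)
            c = np.cov(xy.T)
            c[np.diag_indices_from(c)] += 1e-12  # guard exact degeneracy
            covs[sp] = c
        return cls(species, means, covs, {s: masses[s] for s in species})

    def to_dict(self) -> dict:
        return {
            s: dict(
                mean=self.means[s].tolist(),
                cov=self.covs[s].tolist(),
                nominal_mass=self.masses[s],
            )
            for s in self.species
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassModel":
        species = sorted(d)
        return cls(
            species,
            {s: np.asarray(d[s]["mean"], float) for s in species},
            {s: np.asarray(d[s]["cov"], float) for s in species},
            {s: float(d[s]["nominal_mass"]) for s in species},
        )


def classify_species(
    delta_ires: float, rms_corr: float, class_model: ClassModel,
    ambiguity_ratio: float = AMBIGUITY_RATIO,
) -> str:
    """Maximum-likelihood species in the (dIres%, rms) plane.

    Returns ``"ambiguous"`` when the likelihood ratio between the top two
    species is below ``ambiguity_ratio`` — forced calls in overlapping
    clouds would be meaningless.
    """
    if not class_model.species:
        raise ValueError("class model has no fitted species")
    pt = np.array([delta_ires, rms_corr])
    ll = np.array(
        [
            _st.multivariate_normal.logpdf(pt, class_model.means[s], class_model.covs[s])
            for s in class_model.species
        ]
    )
    order = np.argsort(ll)[::-1]
    if len(ll) > 1 and ll[order[0]] - ll[order[1]] < np.log(ambiguity_ratio):
        return "ambiguous"
    return class_model.species[order[0]]


def call_events(
    stats: pd.DataFrame,
    class_model: ClassModel | None = None,
    z_min: float = Z_MIN_DEFAULT,
) -> list[PTMCall]:
    """Localize (and, with a class model, classify) every eligible event."""
    calls = []
    for eid in sorted(stats.event_id.unique()):
        a1 = a1_table(stats, eid)
        if len(a1[a1.dwell_ms >= MIN_A1_DWELL_MS]) < 3:
            continue
        call = locate_modified_unit(stats, eid, z_min)
        if call.modified_feature_idx is not None and class_model is not None:
            call.species_call = classify_species(call.delta_ires, call.rms_corr, class_model)
        calls.append(call)
    return calls


def calls_to_frame(calls: list[PTMCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                event_id=c.event_id,
                modified_feature_idx=-1 if c.modified_feature_idx is None else c.modified_feature_idx,
                delta_ires=np.nan if c.delta_ires is None else c.delta_ires,
                rms_corr=np.nan if c.rms_corr is None else c.rms_corr,
                species_call=c.species_call,
                score=c.score,
                multi_candidate=c.multi_candidate,
            )
            for c in calls
        ],
        columns=[
            "event_id", "modified_feature_idx", "delta_ires", "rms_corr",
            "species_call", "score", "multi_candidate",
        ],
    )


def mass_monotonicity_report(calls: pd.DataFrame, masses: dict) -> tuple[pd.DataFrame, float]:
    """Mean dIres% per species (with 95% CI) and the mass-rank correlation.

    Requires >= 2 species with >= 10 located calls each. The Spearman rank
    correlation is computed between species mass and mean dIres% (midranks
    under ties); a perfect mass-proportional blockade ordering gives rho=1.
    """
    located = calls[calls.modified_feature_idx >= 0].copy()
    located["species"] = located.species_call
    counts = located.groupby("species").size()
    usable = [s for s in counts.index if counts[s] >= 10 and s in masses]
    if len(usable) < 2:
        raise ValueError(
            "mass monotonicity needs >= 2 species with >= 10 located calls each"
        )
    rows = []
    for sp in usable:
        d = located.loc[located.species == sp, "delta_ires"].to_numpy()
        sem = d.std(ddof=1) / np.sqrt(d.size)
        rows.append(
            dict(
                species=sp,
                nominal_mass=masses[sp],
                n=d.size,
                mean_delta_ires=d.mean(),
                ci_lo=d.mean() - 1.96 * sem,
                ci_hi=d.mean() + 1.96 * sem,
            )
        )
    table = pd.DataFrame(rows).sort_values("nominal_mass", ignore_index=True)
    rho = _st.spearmanr(table.nominal_mass, table.mean_delta_ires).statistic
    return table, float(rho)
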