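"""Synthetic prescriber cohorts with a known structural adoption process.

The generator produces everything the real study consumed -- a physician
roster with covariates, shared-patient pair counts by payer, group/hospital
affiliations, training histories, and quarterly prescribing counts -- from a
linear-in-means structural equation with known peer-effect coefficients, so
that every downstream stage (network construction, the median adoption rule,
2SLS estimation, the social multiplier) has a recoverable ground truth.

Adoption propensities solve the simultaneous system

    p = clip(b0 + X beta + sum_k gamma_k W_k p + u, 0.01, 0.99)

where W_k are the row-stochastic influence matrices of the four networks and
u optionally contains a community-level shared shock (a peer-correlated
confounder).  With sum_k |gamma_k| < 1 the map is a contraction, so the fixed
point is unique.  Observed adoption is an independent Bernoulli draw from the
equilibrium propensity: those draws act as classical measurement error in the
observed peer adoption rates, uncorrelated with peer-mean characteristics, so
two-stage least squares remains consistent while naive OLS does not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .config import NETWORK_KINDS, SimulationConfig
from .networks import (
    InfluenceMatrix,
    PeerNetwork,
    build_affiliation_network,
    build_patient_sharing_network,
    build_training_network,
    row_normalize,
)

CLIP = (0.01, 0.99)
REFERENCE_YEAR = 2011  # cohort age measured at the end of the study window

PAYER_LEVELS = ("medicare", "medicaid")
SPECIALTY_LEVELS = ("pcp", "specialist", "other")


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to converge; carries the residual."""

    def __init__(self, residual: float, max_iter: int):
        super().__init__(
            f"structural fixed point not converged after {max_iter} iterations "
            f"(residual {residual:.3e})"
        )
        self.residual = residual


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    """Independent, reproducible stream per generation stage."""
    return np.random.default_rng([stage, config.seed])


def _dirichlet_rows(rng: np.random.Generator, alphas: np.ndarray) -> np.ndarray:
    """Row-wise Dirichlet draws with per-row concentration parameters."""
    g = rng.gamma(alphas)
    return g / g.sum(axis=1, keepdims=True)


# ----------------------------------------------------------------------
# roster
# ----------------------------------------------------------------------

def generate_physicians(config: SimulationConfig) -> pd.DataFrame:
    """Generate the physician roster with covariates and linkage identifiers.

    Covariates emulate a prescriber cohort: sex, graduation year, specialty
    (primary care / relevant specialist / other), training institutions,
    location, right-skewed prescribing volume, and payer / patient-age mixes
    that each sum to one.  Columns suffixed ``_std`` are cohort z-scores.
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = _rng(config, 1)
    n = config.n_physicians
    n_loc = config.resolved_n_locations
    cpl = config.communities_per_location
    lo, hi = config.grad_year_range

    grad_year = rng.integers(lo, hi + 1, n)
    residency_year = grad_year + rng.integers(3, 7, n)
    specialty_idx = rng.choice(3, size=n, p=list(config.specialty_shares))
    location_idx = rng.integers(0, n_loc, n)
    community_idx = location_idx * cpl + rng.integers(0, cpl, n)
    us_school = (rng.random(n) < 0.78).astype(int)
    volume = rng.lognormal(mean=4.7, sigma=0.6, size=n)
    # payer mix is spatially structured like real markets: the Medicare
    # weight gets a community-level multiplier, so physicians practicing in
    # the same neighborhood face similar patient panels
    spread = np.sqrt(3.0) * config.payer_community_sd
    com_medicare = rng.uniform(1.0 - spread, 1.0 + spread, n_loc * cpl)
    alphas = np.tile((0.6, 7.0, 0.9, 5.5), (n, 1))
    alphas[:, 3] *= com_medicare[community_idx]
    payer_mix = _dirichlet_rows(rng, alphas)
    age_mix = rng.dirichlet((4.3, 2.6, 3.0, 1.6), size=n)

    years = REFERENCE_YEAR - grad_year
    logv = np.log(volume)

    def z(x: np.ndarray) -> np.ndarray:
        s = x.std()
        return (x - x.mean()) / (s if s > 0 else 1.0)

    table = pd.DataFrame(
        {
            "physician_id": [f"P{i:05d}" for i in range(n)],
            "female": (rng.random(n) < 0.25).astype(int),
            "grad_year": grad_year,
            "years_since_grad": years,
            "years_since_grad_std": z(years.astype(float)),
            "specialty": np.array(SPECIALTY_LEVELS)[specialty_idx],
            "specialist": (specialty_idx == 1).astype(int),
            "school_id": np.char.add("S", rng.integers(0, config.n_schools, n).astype(str)),
            "school_grad_year": grad_year,
            "residency_id": np.char.add("R", rng.integers(0, config.n_residencies, n).astype(str)),
            "residency_year": residency_year,
            "location": np.char.add("L", location_idx.astype(str)),
            "community": np.char.add("C", community_idx.astype(str)),
            "us_school": us_school,
            "top20_school": (us_school * (rng.random(n) < 0.13)).astype(int),
            "rural": (rng.random(n) < 0.11).astype(int),
            "cash_share": payer_mix[:, 0],
            "commercial_share": payer_mix[:, 1],
            "medicaid_share": payer_mix[:, 2],
            "medicare_share": payer_mix[:, 3],
            "page_0_64": age_mix[:, 0],
            "page_65_74": age_mix[:, 1],
            "page_75_84": age_mix[:, 2],
            "page_85p": age_mix[:, 3],
            "volume": volume,
            "log_volume_std": z(logv),
        }
    )
    return table


# ----------------------------------------------------------------------
# patient sharing
# ----------------------------------------------------------------------

def shared_patient_counts(assignments: pd.DataFrame) -> pd.DataFrame:
    """Pair counts of unique shared patients by payer.

    ``assignments`` has one row per (patient_id, payer, physician_id); the
    result has one row per unordered physician pair and payer with the number
    of distinct patients both physicians saw under that payer.
    """
    a = assignments.drop_duplicates(["patient_id", "physician_id"])
    merged = a.merge(a, on=["patient_id", "payer"], suffixes=("_a", "_b"))
    merged = merged[merged["physician_id_a"] < merged["physician_id_b"]]
    counts = (
        merged.groupby(["physician_id_a", "physician_id_b", "payer"])["patient_id"]
        .nunique()
        .reset_index(name="n_unique_patients")
        .rename(columns={"physician_id_a": "physician_a", "physician_id_b": "physician_b"})
    )
    return counts


def _group_sampler(codes: np.ndarray):
    """Uniform sampling from the group of a given member, vectorized.

    Returns a function mapping (member_codes, uniform_draws) -> sampled
    member index from the same group.
    """
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    starts = np.searchsorted(sorted_codes, np.arange(codes.max() + 1), side="left")
    ends = np.searchsorted(sorted_codes, np.arange(codes.max() + 1), side="right")
    sizes = ends - starts

    def sample(member_codes: np.ndarray, u: np.ndarray) -> np.ndarray:
        offs = (u * sizes[member_codes]).astype(int)
        return order[starts[member_codes] + offs]

    return sample


def generate_patient_sharing(
    config: SimulationConfig, physicians: pd.DataFrame
) -> pd.DataFrame:
    """Assign synthetic patients to physicians and emit shared-patient counts.

    Each patient gets a payer (Medicare or Medicaid) and 1..k physicians; k is
    driven by ``sharing_concentration`` and extra physicians are drawn with a
    bias toward the first physician's community and location, so same-area
    pairs share more patients.  Rows are unordered pairs, one per pair and
    payer, counting unique patients.
    """
    if len(physicians) == 0:
        raise ValueError("physicians roster is empty")
    rng = _rng(config, 2)
    n_pat = config.resolved_n_patients
    n_phys = len(physicians)

    payer = np.array(PAYER_LEVELS)[(rng.random(n_pat) < 0.4).astype(int)]
    n_docs = 1 + rng.poisson(config.sharing_concentration - 1.0, n_pat)
    n_docs = np.minimum(n_docs, 6)

    first = rng.integers(0, n_phys, n_pat)
    loc_codes = pd.factorize(physicians["location"], sort=True)[0]
    com_codes = pd.factorize(physicians["community"], sort=True)[0]
    sample_loc = _group_sampler(loc_codes)
    sample_com = _group_sampler(com_codes)

    extra_counts = n_docs - 1
    total_extra = int(extra_counts.sum())
    if total_extra == 0:
        return pd.DataFrame(
            columns=["physician_a", "physician_b", "payer", "n_unique_patients"]
        )
    owner = np.repeat(np.arange(n_pat), extra_counts)  # patient of each extra slot
    anchor = first[owner]
    mode = rng.random(total_extra)
    u = rng.random(total_extra)
    extra = rng.integers(0, n_phys, total_extra)
    com_mask = mode < config.same_community_prob
    loc_mask = (~com_mask) & (mode < config.same_community_prob + config.same_location_prob)
    extra[com_mask] = sample_com(com_codes[anchor[com_mask]], u[com_mask])
    extra[loc_mask] = sample_loc(loc_codes[anchor[loc_mask]], u[loc_mask])

    ids = physicians["physician_id"].to_numpy()
    assignments = pd.DataFrame(
        {
            "patient_id": np.concatenate([np.arange(n_pat), owner]),
            "payer": np.concatenate([payer, payer[owner]]),
            "physician_id": np.concatenate([ids[first], ids[extra]]),
        }
    )
    return shared_patient_counts(assignments)


# ----------------------------------------------------------------------
# affiliations
# ----------------------------------------------------------------------

def generate_affiliations(
    config: SimulationConfig, physicians: pd.DataFrame
) -> pd.DataFrame:
    """Assign group and hospital memberships, stratified by location.

    Medical groups are small (about ten physicians) and hospitals large;
    organizations belong to a single location and physicians only join
    organizations in their own location, which keeps cross-network edge
    overlap low.  Coverage probabilities default to the 72% / 90% group and
    hospital affiliation rates typical of prescriber cohorts.
    """
    if len(physicians) == 0:
        raise ValueError("physicians roster is empty")
    rng = _rng(config, 3)
    n = len(physicians)
    n_loc = config.resolved_n_locations
    loc_codes = pd.factorize(physicians["location"], sort=True)[0]
    ids = physicians["physician_id"].to_numpy()
    rows: list[pd.DataFrame] = []

    def org_membership(n_orgs: int, kind: str, coverage: float, second_prob: float):
        # organization o sits in location o % n_loc
        org_loc = np.arange(n_orgs) % n_loc
        member = rng.random(n) < coverage
        per_loc = [np.flatnonzero(org_loc == l) for l in range(n_loc)]
        counts = np.array([len(p) for p in per_loc])
        idx = np.flatnonzero(member & (counts[loc_codes] > 0))
        local_n = counts[loc_codes[idx]]
        pick = (rng.random(len(idx)) * local_n).astype(int)
        org_of = np.array(
            [per_loc[loc_codes[i]][p] for i, p in zip(idx, pick)], dtype=int
        ) if len(idx) else np.array([], dtype=int)
        frames = [pd.DataFrame({"physician_id": ids[idx], "organization_id": org_of})]
        if second_prob > 0 and len(idx):
            again = rng.random(len(idx)) < second_prob
            j = idx[again]
            szs = counts[loc_codes[j]]
            ok = szs > 1
            j, szs = j[ok], szs[ok]
            first_pick = pick[again][ok]
            shift = 1 + (rng.random(len(j)) * (szs - 1)).astype(int)
            second_pick = (first_pick + shift) % szs
            org2 = np.array(
                [per_loc[loc_codes[i]][p] for i, p in zip(j, second_pick)], dtype=int
            )
            frames.append(pd.DataFrame({"physician_id": ids[j], "organization_id": org2}))
        out = pd.concat(frames, ignore_index=True)
        prefix = "G" if kind == "group" else "H"
        out["organization_id"] = prefix + out["organization_id"].astype(str)
        out["organization_kind"] = kind
        return out

    rows.append(
        org_membership(config.resolved_n_groups, "group", config.group_coverage, 0.0)
    )
    rows.append(
        org_membership(
            config.resolved_n_hospitals,
            "hospital",
            config.hospital_coverage,
            config.second_hospital_prob,
        )
    )
    out = pd.concat(rows, ignore_index=True)
    return out.drop_duplicates(["physician_id", "organization_id"]).reset_index(drop=True)


# ----------------------------------------------------------------------
# structural adoption process
# ----------------------------------------------------------------------

@dataclass
class SimulationTruth:
    """Ground truth of the structural adoption process.

    ``linear_base`` is the full non-peer part of the linear index (intercept,
    covariate effects and both error components), so the fixed point can be
    re-verified externally: p == clip(linear_base + sum_k gamma_k W_k p).
    """

    equilibrium_propensity: np.ndarray
    realized_adoption: np.ndarray
    confounder_values: np.ndarray
    linear_base: np.ndarray
    beta0: float
    iterations: int
    residual: float

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "iterations": self.iterations,
            "residual": self.residual,
            "equilibrium_propensity": self.equilibrium_propensity.tolist(),
            "realized_adoption": self.realized_adoption.astype(int).tolist(),
            "confounder_values": self.confounder_values.tolist(),
            "linear_base": self.linear_base.tolist(),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationTruth":
        return cls(
            equilibrium_propensity=np.asarray(data["equilibrium_propensity"], float),
            realized_adoption=np.asarray(data["realized_adoption"], int),
            confounder_values=np.asarray(data["confounder_values"], float),
            linear_base=np.asarray(data["linear_base"], float),
            beta0=float(data["beta0"]),
            iterations=int(data["iterations"]),
            residual=float(data["residual"]),
        )


def structural_map(
    p: np.ndarray, base: np.ndarray, peer_term, clip: tuple[float, float] = CLIP
) -> np.ndarray:
    """One application of p -> clip(base + sum_k gamma_k W_k p)."""
    return np.clip(base + peer_term(p), clip[0], clip[1])


def solve_equilibrium(
    base: np.ndarray,
    influence: Mapping[str, InfluenceMatrix],
    gamma: Mapping[str, float],
    clip: tuple[float, float] = CLIP,
    tol: float = 1e-13,
    max_iter: int = 2000,
    start: np.ndarray | None = None,
) -> tuple[np.ndarray, int, float]:
    """Solve the structural fixed point by iteration.

    With row-stochastic W_k and sum |gamma_k| < 1 the map is a contraction
    (clipping is 1-Lipschitz), so iteration from any start converges to the
    unique fixed point.  Returns (p, iterations, final residual).
    """
    mats = [(gamma[k], influence[k].matrix) for k in influence if gamma.get(k, 0.0) != 0.0]
    if mats:
        combined = sum(g * m for g, m in mats).tocsr()

        def peer_term(p):
            return combined @ p
    else:

        def peer_term(p):
            return 0.0

    p = np.full_like(base, np.mean(clip)) if start is None else start.copy()
    residual = np.inf
    for it in range(1, max_iter + 1):
        nxt = structural_map(p, base, peer_term, clip)
        residual = float(np.max(np.abs(nxt - p)))
        p = nxt
        if residual < tol:
            return p, it, residual
    raise ConvergenceError(residual, max_iter)


def calibrate_intercept(
    base_no_intercept: np.ndarray,
    influence: Mapping[str, InfluenceMatrix],
    gamma: Mapping[str, float],
    target: float,
    tol: float = 0.005,
    clip: tuple[float, float] = CLIP,
) -> tuple[float, np.ndarray, int, float]:
    """Find b0 so the mean equilibrium propensity hits the target rate.

    The mean of the fixed point is monotone in b0; a secant search with a
    bisection fallback converges in a handful of equilibrium solves, each
    warm-started from the previous solution.
    """
    shrink = 1.0 - sum(abs(v) for v in gamma.values())

    state = {"p": None}

    def mean_at(b0: float) -> float:
        p, _, _ = solve_equilibrium(
            base_no_intercept + b0, influence, gamma, clip=clip, start=state["p"]
        )
        state["p"] = p
        return float(p.mean())

    b_prev = target * shrink - float(np.mean(base_no_intercept))
    f_prev = mean_at(b_prev) - target
    b_cur = b_prev + (0.05 if f_prev < 0 else -0.05)
    for _ in range(40):
        f_cur = mean_at(b_cur) - target
        if abs(f_cur) <= tol:
            p, it, res = solve_equilibrium(
                base_no_intercept + b_cur, influence, gamma, clip=clip, start=state["p"]
            )
            return b_cur, p, it, res
        if f_cur == f_prev:  # flat (fully clipped); widen step
            b_prev, b_cur = b_cur, b_cur + (0.5 if f_cur < 0 else -0.5)
            f_prev = f_cur
            continue
        b_next = b_cur - f_cur * (b_cur - b_prev) / (f_cur - f_prev)
        b_next = float(np.clip(b_next, b_cur - 2.0, b_cur + 2.0))
        b_prev, f_prev, b_cur = b_cur, f_cur, b_next
    raise ConvergenceError(abs(f_cur), 40)


def simulate_adoption(
    physicians: pd.DataFrame,
    networks: Mapping[str, "PeerNetwork | InfluenceMatrix"],
    config: SimulationConfig,
    affiliations: pd.DataFrame | None = None,
) -> tuple[SimulationTruth, pd.DataFrame]:
    """Simulate equilibrium adoption and the prescribing table.

    ``networks`` maps network kind to a :class:`PeerNetwork` (row-normalized
    here) or an :class:`InfluenceMatrix`.  When ``confounder_sd`` > 0 the
    error term includes a shock shared within the confounder unit (medical
    groups by default, requiring ``affiliations``; practice communities
    otherwise) -- unobserved factors common among groups of peers.  The
    returned prescribing table has quarterly new-drug and class-level counts
    constructed so that adopters sit at or above, and non-adopters strictly
    below, the median-rule threshold applied downstream.
    """
    config.validate()
    rng = _rng(config, 4)
    n = len(physicians)
    index = physicians["physician_id"]
    influence: dict[str, InfluenceMatrix] = {}
    for kind, net in networks.items():
        influence[kind] = net if isinstance(net, InfluenceMatrix) else row_normalize(net, index)

    base = np.zeros(n)
    for col, coef in config.true_beta.items():
        base += coef * physicians[col].to_numpy(float)

    confounder = _confounder_shocks(config, physicians, affiliations, rng)
    u = confounder + (
        rng.normal(0.0, config.idiosyncratic_sd, n) if config.idiosyncratic_sd > 0 else 0.0
    )

    gamma = {k: config.true_gamma.get(k, 0.0) for k in influence}
    beta0, p, iters, residual = calibrate_intercept(
        base + u, influence, gamma, config.target_adoption_rate,
        clip=config.clip_bounds,
    )

    if config.bernoulli_noise:
        y = (rng.random(n) < p).astype(int)
    else:
        cutoff = np.quantile(p, 1.0 - config.target_adoption_rate)
        y = (p >= cutoff).astype(int)

    prescribing = _generate_prescribing(config, physicians, y, rng)
    truth = SimulationTruth(
        equilibrium_propensity=p,
        realized_adoption=y,
        confounder_values=confounder,
        linear_base=base + u + beta0,
        beta0=float(beta0),
        iterations=iters,
        residual=residual,
    )
    return truth, prescribing


def _confounder_shocks(
    config: SimulationConfig,
    physicians: pd.DataFrame,
    affiliations: pd.DataFrame | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Shared shock per confounder unit; unaffiliated physicians draw alone."""
    n = len(physicians)
    if config.confounder_sd == 0:
        return np.zeros(n)
    if config.confounder_unit == "group" and affiliations is not None:
        groups = affiliations[affiliations["organization_kind"] == "group"]
        first_group = (
            groups.drop_duplicates("physician_id").set_index("physician_id")["organization_id"]
        )
        unit = (
            first_group.reindex(physicians["physician_id"])
            .fillna(pd.Series(  # solo practices: one unit each
                [f"solo{i}" for i in range(n)], index=physicians["physician_id"]
            ))
        )
    else:
        unit = physicians.set_index("physician_id")["community"]
    codes = pd.factorize(unit, sort=True)[0]
    shocks = rng.normal(0.0, config.confounder_sd, codes.max() + 1)
    return shocks[codes]


def _generate_prescribing(
    config: SimulationConfig,
    physicians: pd.DataFrame,
    adoption: np.ndarray,
    rng: np.random.Generator,
    n_quarters: int = 5,
) -> pd.DataFrame:
    """Quarterly counts honoring the median rule and the cohort filter.

    Adopter totals are M + extra with half the mass exactly at the intended
    median M; non-adopters prescribe the new drug at all with a probability
    small enough that adopters are a strict majority of ever-prescribers, so
    the realized cohort median equals M and the median rule recovers truth.
    Class-level counts are at least 1 per quarter so the whole roster passes
    the minimal-prescribing cohort filter.
    """
    n = len(physicians)
    m = config.target_median
    adopt = adoption.astype(bool)
    totals = np.zeros(n, dtype=int)
    extra = np.where(
        rng.random(n) < 0.5, 0, 1 + rng.poisson(3.0, n)
    )
    totals[adopt] = m + extra[adopt]
    non = ~adopt
    q = config.resolved_nonadopter_rx_prob
    writes = non & (rng.random(n) < q) if m > 1 else np.zeros(n, bool)
    totals[writes] = rng.integers(1, m, int(writes.sum()))

    quarters = rng.multinomial(totals, np.full(n_quarters, 1.0 / n_quarters))
    volume = physicians["volume"].to_numpy(float)
    class_q = 1 + rng.poisson(
        np.maximum(volume[:, None] / n_quarters - 1.0, 0.2), size=(n, n_quarters)
    )

    ids = physicians["physician_id"].to_numpy()
    qcol = np.tile(np.arange(1, n_quarters + 1), n)
    frame = pd.DataFrame(
        {
            "physician_id": np.concatenate([np.repeat(ids, n_quarters)] * 2),
            "drug": ["new_drug"] * n * n_quarters + ["class_other"] * n * n_quarters,
            "quarter": np.concatenate([qcol, qcol]),
            "n_prescriptions": np.concatenate([quarters.ravel(), class_q.ravel()]),
        }
    )
    return frame


# ----------------------------------------------------------------------
# the full cohort
# ----------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """All synthetic study inputs plus the generating truth."""

    config: SimulationConfig
    physicians: pd.DataFrame
    shared_patient_records: pd.DataFrame
    affiliations: pd.DataFrame
    prescribing: pd.DataFrame
    truth: SimulationTruth
    networks: dict[str, PeerNetwork]

    def influence(self) -> dict[str, InfluenceMatrix]:
        idx = self.physicians["physician_id"]
        return {k: row_normalize(net, idx) for k, net in self.networks.items()}

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.physicians.to_csv(directory / "physicians.csv", index=False)
        self.shared_patient_records.to_csv(directory / "shared_patients.csv", index=False)
        self.affiliations.to_csv(directory / "affiliations.csv", index=False)
        self.prescribing.to_csv(directory / "prescribing.csv", index=False)
        (directory / "truth.json").write_text(json.dumps(self.truth.to_dict()))
        (directory / "config.yaml").write_text(yaml.safe_dump(self.config.to_dict()))


def build_networks(
    physicians: pd.DataFrame,
    shared_patient_records: pd.DataFrame,
    affiliations: pd.DataFrame,
    min_shared: int = 1,
    year_window: int = 1,
) -> dict[str, PeerNetwork]:
    """Build all four peer networks from record tables."""
    nodes = list(physicians["physician_id"])
    return {
        "P": build_patient_sharing_network(shared_patient_records, nodes, min_shared),
        "G": build_affiliation_network(affiliations, "G", nodes),
        "H": build_affiliation_network(affiliations, "H", nodes),
        "T": build_training_network(physicians, year_window, nodes),
    }


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a complete synthetic cohort: roster, records, networks, truth."""
    physicians = generate_physicians(config)
    records = generate_patient_sharing(config, physicians)
    affiliations = generate_affiliations(config, physicians)
    networks = build_networks(physicians, records, affiliations)
    truth, prescribing = simulate_adoption(physicians, networks, config, affiliations)
    return SyntheticCohort(
        config=config,
        physicians=physicians,
        shared_patient_records=records,
        affiliations=affiliations,
        prescribing=prescribing,
        truth=truth,
        networks=networks,
    )


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Reload a cohort written by :meth:`SyntheticCohort.write`."""
    directory = Path(directory)
    config = SimulationConfig.from_file(directory / "config.yaml")
    physicians = pd.read_csv(directory / "physicians.csv")
    records = pd.read_csv(directory / "shared_patients.csv")
    affiliations = pd.read_csv(directory / "affiliations.csv")
    prescribing = pd.read_csv(directory / "prescribing.csv")
    truth = SimulationTruth.from_dict(json.loads((directory / "truth.json").read_text()))
    networks = build_networks(physicians, records, affiliations)
    return SyntheticCohort(
        config, physicians, records, affiliations, prescribing, truth, networks
    )


# ----------------------------------------------------------------------
# compact IV benchmark process
# ----------------------------------------------------------------------

def simulate_linear_iv(
    n: int,
    seed: int,
    n_instruments: int = 4,
    first_stage_strength: float = 0.4,
    gamma: float = 0.5,
    endogeneity: float = 0.5,
    contamination: float = 0.0,
) -> pd.DataFrame:
    """A stripped-down linear IV data process for estimator validation.

    y = 1 + 0.5 x + gamma d + u;  d = pi' z + 0.5 x + v with corr(u, v) =
    ``endogeneity`` (so OLS on d is biased while 2SLS is consistent).  When
    ``contamination`` > 0 the last instrument is shifted by that multiple of
    the structural error, violating exogeneity -- the regime in which an
    overidentification test should reject.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.normal(size=(n, n_instruments))
    u = rng.normal(size=n)
    v = endogeneity * u + np.sqrt(max(1 - endogeneity**2, 0.0)) * rng.normal(size=n)
    if contamination:
        z[:, -1] += contamination * u
    d = z @ np.full(n_instruments, first_stage_strength) + 0.5 * x + v
    y = 1.0 + 0.5 * x + gamma * d + u
    data = pd.DataFrame({"y": y, "x": x, "d": d})
    for j in range(n_instruments):
        data[f"z{j + 1}"] = z[:, j]
    return data
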