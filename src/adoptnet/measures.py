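"""Adoption classification and per-physician peer measures.

Implements the median rule (adopter = at least the cohort median number of
new-drug prescriptions among physicians who prescribed it at least once in
the first five quarters on the market), and all peer quantities entering the
linear-in-means model: per-network peer adoption rates, no-peer indicators,
peer specialty / volume composition controls, and the peer-mean instrument
columns.  Patient-sharing quantities are weighted by the influence matrix;
for the equal-influence networks the weighted and unweighted means coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .networks import InfluenceMatrix

#: peer characteristics that may never serve as instruments: specialty mix
#: and prescribing volume are believed to influence adoption directly.
ENDOGENOUS_ADJACENT = {"specialist", "specialty", "high_volume", "volume", "log_volume_std"}

#: exogenous peer characteristics averaged into instruments by default:
#: peer sex composition and the peer payer mix.  Both are plausibly excluded
#: from a physician's own adoption decision, and the payer mix varies across
#: practice communities, which is what gives the instruments their power.
DEFAULT_INSTRUMENT_SOURCES = (
    "female",
    "medicare_share",
)

#: physician-level covariates entering the outcome model by default.
DEFAULT_COVARIATES = (
    "female",
    "years_since_grad_std",
    "us_school",
    "top20_school",
    "rural",
    "cash_share",
    "medicaid_share",
    "medicare_share",
    "page_65_74",
    "page_75_84",
    "page_85p",
    "specialist",
    "high_volume",
)

ADOPTION_WINDOW_QUARTERS = 5  # first 15 months on the market


class EmptySupportError(ValueError):
    """No physician prescribed the drug: the median threshold is undefined."""


class AlignmentError(ValueError):
    """Influence matrix and outcome vector are not index-aligned."""


class SpecificationError(ValueError):
    """A forbidden column was passed where an exogenous one is required."""


@dataclass
class AdoptionOutcome:
    """Binary adopter flags with the rule that produced them."""

    y: pd.Series  # indexed by physician_id, values 0/1
    threshold: int
    window_quarters: int = ADOPTION_WINDOW_QUARTERS


def _window_totals(prescribing: pd.DataFrame, window_quarters: int, drug: str) -> pd.Series:
    rows = prescribing[
        (prescribing["drug"] == drug) & (prescribing["quarter"] <= window_quarters)
    ]
    return rows.groupby("physician_id")["n_prescriptions"].sum()


def compute_adoption_threshold(
    prescribing: pd.DataFrame, window_quarters: int = ADOPTION_WINDOW_QUARTERS
) -> int:
    """Median-rule threshold: lower median of new-drug totals among prescribers.

    Only physicians with at least one new-drug prescription inside the window
    enter the median; the lower median is used for even counts so the
    threshold is always an attained integer count.
    """
    if window_quarters < 1:
        raise ValueError("window must cover at least one quarter")
    totals = _window_totals(prescribing, window_quarters, "new_drug")
    totals = totals[totals >= 1]
    if len(totals) == 0:
        raise EmptySupportError("no physician prescribed the new drug in the window")
    ordered = np.sort(totals.to_numpy())
    return int(ordered[(len(ordered) - 1) // 2])


def classify_adopters(
    prescribing: pd.DataFrame,
    threshold: "int | str" = "median",
    physicians: Sequence[str] | None = None,
    window_quarters: int = ADOPTION_WINDOW_QUARTERS,
) -> AdoptionOutcome:
    """Flag adopters: new-drug window total >= threshold.

    ``threshold`` may be an integer or a rule name: ``"median"`` (the default
    median rule), ``"ge1"``, ``"ge15"`` (the robustness variants).  Physicians
    with zero new-drug prescriptions are never adopters.
    """
    if isinstance(threshold, str):
        rule = threshold.replace(">=", "ge").replace(" ", "")
        if rule == "median":
            thr = compute_adoption_threshold(prescribing, window_quarters)
        elif rule in {"ge1", "1"}:
            thr = 1
        elif rule in {"ge15", "15"}:
            thr = 15
        else:
            raise ValueError(f"unknown adoption rule {threshold!r}")
    else:
        thr = int(threshold)
    if thr < 1:
        raise ValueError("adoption threshold must be >= 1")
    totals = _window_totals(prescribing, window_quarters, "new_drug")
    if physicians is None:
        physicians = prescribing["physician_id"].unique()
    index = pd.Index(physicians, name="physician_id")
    totals = totals.reindex(index, fill_value=0)
    y = (totals >= thr).astype(int).rename("adopter")
    return AdoptionOutcome(y=y, threshold=thr, window_quarters=window_quarters)


def _check_alignment(W: InfluenceMatrix, values: pd.Series) -> np.ndarray:
    if isinstance(values, pd.Series):
        if len(values) != W.n or not values.index.equals(W.index):
            if set(values.index) != set(W.index):
                raise AlignmentError("outcome index does not match influence matrix index")
            values = values.reindex(W.index)
        return values.to_numpy(float)
    arr = np.asarray(values, float)
    if len(arr) != W.n:
        raise AlignmentError(
            f"length {len(arr)} does not match influence matrix size {W.n}"
        )
    return arr


def peer_adoption_rate(
    W: InfluenceMatrix, outcome: "AdoptionOutcome | pd.Series"
) -> tuple[pd.Series, pd.Series]:
    """Weighted fraction of a physician's peers who adopted.

    Returns (rate, no-peer indicator); physicians with no peers in the
    network get rate 0 and indicator 1 (the model's imputation convention).
    """
    y = outcome.y if isinstance(outcome, AdoptionOutcome) else outcome
    arr = _check_alignment(W, y)
    rate = np.clip(W.dot(arr), 0.0, 1.0)  # convex combination of 0/1 flags
    rate[W.no_peer] = 0.0
    return (
        pd.Series(rate, index=W.index, name="peer_adoption_rate"),
        pd.Series(W.no_peer.astype(int), index=W.index, name="no_peer"),
    )


def peer_composition(
    W: InfluenceMatrix,
    specialist_flag: pd.Series,
    high_volume_flag: pd.Series,
) -> pd.DataFrame:
    """Peer shares of relevant specialists and of high-volume prescribers.

    Uses the same weighting as the peer adoption rate (patient-count weights
    in P, equal weights elsewhere); zero-imputed for isolates.
    """
    c = np.clip(W.dot(_check_alignment(W, specialist_flag)), 0.0, 1.0)
    v = np.clip(W.dot(_check_alignment(W, high_volume_flag)), 0.0, 1.0)
    c[W.no_peer] = 0.0
    v[W.no_peer] = 0.0
    return pd.DataFrame({"cbar": c, "vbar": v}, index=W.index)


def peer_mean_instruments(
    W: InfluenceMatrix,
    X_exog: pd.DataFrame,
    forbidden: set[str] | None = None,
) -> pd.DataFrame:
    """Peer means of exogenous characteristics (the instrument columns).

    Specialty-mix and prescribing-volume columns are refused: they are held
    to influence adoption directly, so they enter the model as controls, not
    instruments.  Zero-imputed for isolates (paired with the no-peer
    indicator in the design matrix).
    """
    bad = set(X_exog.columns) & (ENDOGENOUS_ADJACENT | (forbidden or set()))
    if bad:
        raise SpecificationError(
            f"columns {sorted(bad)} may not be used as instruments: specialty mix "
            "and prescribing volume are direct influences, not exclusions"
        )
    out = {}
    for col in X_exog.columns:
        vals = W.dot(_check_alignment(W, X_exog[col]))
        vals[W.no_peer] = 0.0
        out[col] = vals
    return pd.DataFrame(out, index=W.index)


@dataclass
class ModelSpec:
    """Column lists defining the outcome model and its instrument set."""

    outcome: str
    endog: list[str]
    exog: list[str]
    instruments: list[str]
    robust: str = "HC1"
    unreliable: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        sets = [set(self.endog), set(self.exog), set(self.instruments)]
        for i in range(3):
            for j in range(i + 1, 3):
                common = sets[i] & sets[j]
                if common:
                    raise SpecificationError(
                        f"endogenous / exogenous / instrument sets overlap: {sorted(common)}"
                    )
        if self.outcome in sets[0] | sets[1] | sets[2]:
            raise SpecificationError("outcome column reappears among regressors")
        if len(self.instruments) < len(self.endog):
            raise SpecificationError(
                f"order condition violated: {len(self.instruments)} instruments for "
                f"{len(self.endog)} endogenous columns"
            )


def build_analysis_table(
    physicians: pd.DataFrame,
    influence: Mapping[str, InfluenceMatrix],
    prescribing: pd.DataFrame,
    adoption_rule: "int | str" = "median",
    instrument_sources: Sequence[str] = DEFAULT_INSTRUMENT_SOURCES,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    window_quarters: int = ADOPTION_WINDOW_QUARTERS,
) -> tuple[pd.DataFrame, ModelSpec, AdoptionOutcome]:
    """Assemble the single per-physician analysis table and its model spec.

    Columns: the adoption outcome ``adopter``; per network k in P/G/H/T the
    peer adoption rate ``ybar_k``, no-peer indicator ``nopeer_k``, specialist
    share ``cbar_k``, high-volume share ``vbar_k`` and instrument columns
    ``iv_k_<characteristic>``; plus the physician covariates.  ``high_volume``
    is class-level window prescribing at or above the cohort median.
    """
    table = physicians.set_index("physician_id").copy()
    class_totals = _window_totals(prescribing, window_quarters, "class_other").reindex(
        table.index, fill_value=0
    )
    new_totals = _window_totals(prescribing, window_quarters, "new_drug").reindex(
        table.index, fill_value=0
    )
    class_volume = class_totals + new_totals
    table["class_volume"] = class_volume
    table["high_volume"] = (class_volume >= class_volume.median()).astype(int)

    outcome = classify_adopters(
        prescribing, adoption_rule, physicians=table.index, window_quarters=window_quarters
    )
    table["adopter"] = outcome.y

    endog, instruments, extra_exog = [], [], []
    for kind, W in influence.items():
        rate, nopeer = peer_adoption_rate(W, outcome.y)
        comp = peer_composition(W, table["specialist"], table["high_volume"])
        ivs = peer_mean_instruments(W, table[list(instrument_sources)])
        table[f"ybar_{kind}"] = rate
        table[f"nopeer_{kind}"] = nopeer
        table[f"cbar_{kind}"] = comp["cbar"]
        table[f"vbar_{kind}"] = comp["vbar"]
        endog.append(f"ybar_{kind}")
        extra_exog += [f"cbar_{kind}", f"vbar_{kind}", f"nopeer_{kind}"]
        for col in instrument_sources:
            name = f"iv_{kind}_{col}"
            table[name] = ivs[col]
            instruments.append(name)

    # constant columns (e.g. a no-peer indicator when nobody is isolated)
    # carry no information and break the full-rank precondition
    def varying(cols: list[str]) -> list[str]:
        return [c for c in cols if table[c].nunique() > 1]

    spec = ModelSpec(
        outcome="adopter",
        endog=endog,
        exog=varying(list(covariates) + extra_exog),
        instruments=varying(instruments),
    )
    return table.reset_index(), spec, outcome
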