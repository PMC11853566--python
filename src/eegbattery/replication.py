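"""Split-half replication rate of supra-threshold effects.

An effect "replicates" in one split when its type-III partial eta² exceeds
the threshold in both stratified halves; the replication rate is the
fraction of such splits over (by default) 150 seeded random splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from eegbattery.stats import (
    AGE_GROUPS,
    AgeGrouping,
    DESIGNATED_TERMS,
    AUTISTIC,
    fit_term_eta2,
    lrt_age_quadratic,
    remove_outliers,
)

ETA2_THRESHOLD = 0.035
#: Replication-rate acceptance threshold: square of the 0.80 power convention.
RATE_THRESHOLD = 0.64


@dataclass
class SplitPlan:
    """One stratified half-split of a participant set."""

    seed: int
    half_a: list[str]
    half_b: list[str]

    def __post_init__(self) -> None:
        if set(self.half_a) & set(self.half_b):
            raise ValueError("halves must be disjoint")


def _age_deciles(ages: np.ndarray, n_bins: int = 10) -> np.ndarray:
    qs = np.quantile(ages, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, ages, side="left")


def stratified_split(demographics: pd.DataFrame, seed: int) -> SplitPlan:
    """Half-split preserving diagnosis, sex, and age-decile composition.

    Within each (diagnosis x sex x age-decile) cell, members are shuffled
    under the seed and assigned alternately; odd cells alternate which half
    receives the surplus member.  Deterministic under seed.
    """
    rng = np.random.default_rng(seed)
    demo = demographics.sort_values("participant_id", kind="mergesort")
    decile = _age_deciles(demo["age_months"].to_numpy(dtype=float))
    cells: dict[tuple, list[str]] = {}
    for pid, diag, sex, dec in zip(
        demo["participant_id"], demo["diagnosis"], demo["sex"], decile
    ):
        cells.setdefault((diag, sex, int(dec)), []).append(pid)

    half_a: list[str] = []
    half_b: list[str] = []
    surplus_to_a = True
    for key in sorted(cells):
        members = list(cells[key])
        rng.shuffle(members)
        if len(members) % 2 == 1:
            first_half_a = surplus_to_a
            surplus_to_a = not surplus_to_a
        else:
            first_half_a = True
        for i, pid in enumerate(members):
            if (i % 2 == 0) == first_half_a:
                half_a.append(pid)
            else:
                half_b.append(pid)
    return SplitPlan(seed=seed, half_a=half_a, half_b=half_b)


@dataclass
class ReplicationSummary:
    variable: str
    age_group: str
    model: str
    term: str
    full_eta2: float
    rate: float
    n_splits: int
    eta2_threshold: float
    rate_threshold: float


def replication_rate(
    values: np.ndarray,
    demographics: pd.DataFrame,
    model: str,
    term: str,
    use_age2: bool,
    n_splits: int = 150,
    threshold: float = ETA2_THRESHOLD,
    seed: int = 0,
) -> float:
    """Fraction of stratified splits with eta² > threshold in both halves.

    `values` and `demographics` are one variable's age-group data after
    outlier removal; the Age² decision is frozen from the full-data fit.
    Half-fit failures count as non-replication.
    """
    demo = demographics.reset_index(drop=True)
    pid_to_row = {pid: i for i, pid in enumerate(demo["participant_id"])}
    values = np.asarray(values, dtype=float)
    seeds = np.random.SeedSequence(seed).spawn(n_splits)
    successes = 0
    for s in range(n_splits):
        plan = stratified_split(demo, int(seeds[s].generate_state(1)[0]))
        ok = True
        for half in (plan.half_a, plan.half_b):
            rows = [pid_to_row[p] for p in half]
            try:
                eta2, _ = fit_term_eta2(
                    values[rows], demo.iloc[rows], model, term, use_age2
                )
            except Exception:  # noqa: BLE001 - counts as non-replication
                ok = False
                break
            if not np.isfinite(eta2) or eta2 <= threshold:
                ok = False
                break
        successes += ok
    return successes / n_splits


def prepare_variable(
    features: pd.DataFrame,
    demographics: pd.DataFrame,
    grouping: AgeGrouping,
    variable: str,
    age_group: str,
    z_threshold: float = 3.5,
) -> tuple[np.ndarray, pd.DataFrame, bool]:
    """Reconstruct one (variable, age group)'s modelling data.

    Applies the same complete-case and outlier screening as the effect
    sweep and re-derives the Age² decision; returns (values, demographics
    subset, use_age2).
    """
    feat = features.set_index("participant_id")
    demo = demographics.set_index("participant_id")
    ids = [pid for pid in grouping.ids_in(age_group) if pid in feat.index]
    y = feat.loc[ids, variable].to_numpy(dtype=float)
    d = demo.loc[ids]
    complete = np.isfinite(y)
    y, d = y[complete], d[complete]
    keep, _ = remove_outliers(y, d["diagnosis"].to_numpy(), z_threshold)
    y, d = y[keep], d[keep]
    use_age2, _, _ = lrt_age_quadratic(y, d["age_months"].to_numpy())
    return y, d.reset_index(), use_age2


def replicate_effects(
    effects: pd.DataFrame,
    features: pd.DataFrame,
    demographics: pd.DataFrame,
    grouping: AgeGrouping,
    n_splits: int = 150,
    threshold: float = ETA2_THRESHOLD,
    rate_threshold: float = RATE_THRESHOLD,
    seed: int = 0,
    z_threshold: float = 3.5,
) -> pd.DataFrame:
    """Replication summaries for every supra-threshold effect in a table."""
    supra = effects[(effects["eta2"] > threshold) & effects["eta2"].notna()]
    seeds = np.random.SeedSequence(seed).spawn(len(supra))
    rows = []
    for i, (_, rec) in enumerate(supra.iterrows()):
        y, d, use_age2 = prepare_variable(
            features, demographics, grouping, rec["variable"], rec["age_group"], z_threshold
        )
        rate = replication_rate(
            y,
            d,
            rec["model"],
            rec["term"],
            use_age2,
            n_splits=n_splits,
            threshold=threshold,
            seed=int(seeds[i].generate_state(1)[0]),
        )
        rows.append(
            ReplicationSummary(
                variable=rec["variable"],
                age_group=rec["age_group"],
                model=rec["model"],
                term=rec["term"],
                full_eta2=float(rec["eta2"]),
                rate=rate,
                n_splits=n_splits,
                eta2_threshold=threshold,
                rate_threshold=rate_threshold,
            ).__dict__
        )
    columns = [
        "variable", "age_group", "model", "term", "full_eta2",
        "rate", "n_splits", "eta2_threshold", "rate_threshold",
    ]
    return pd.DataFrame(rows, columns=columns)


def select_replicable(
    summaries: pd.DataFrame,
    rate_threshold: float = RATE_THRESHOLD,
    eta2_threshold: float = ETA2_THRESHOLD,
) -> pd.DataFrame:
    """Effects with eta² above threshold and rate >= rate_threshold.

    The rate boundary is inclusive ("at least"); output is sorted by age
    group (youngest -> oldest), then descending rate.
    """
    if summaries.empty:
        return summaries.copy()
    sel = summaries[
        (summaries["full_eta2"] > eta2_threshold)
        & (summaries["rate"] >= rate_threshold)
    ].copy()
    order = {g: i for i, g in enumerate(AGE_GROUPS)}
    sel["_o"] = sel["age_group"].map(order)
    sel = sel.sort_values(["_o", "rate"], ascending=[True, False]).drop(columns="_o")
    return sel.reset_index(drop=True)
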