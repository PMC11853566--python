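"""Sample-size subsampling, supra-threshold patterns, NMI, and matching.

Quantifies how effect-size prevalence and pattern replicability vary with
sample size: repeated stratified subsampling at several fractions, per-term
proportions of supra-threshold effects, pairwise normalized mutual
information between supra-threshold patterns, and a demographically matched
case-control subset.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from eegbattery.stats import AGE_GROUPS, AgeGrouping, effect_table

ETA2_THRESHOLD = 0.035
DEFAULT_FRACTIONS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)


def subsample(demographics: pd.DataFrame, fraction: float, seed: int) -> list[str]:
    """Without-replacement subsample preserving diagnosis x sex proportions.

    Cell quotas are allocated by the largest-remainder method so the total
    equals round(fraction * n); a non-empty cell whose quota lands at zero
    is skipped with a warning.  Deterministic under seed.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    demo = demographics.sort_values("participant_id", kind="mergesort")
    if fraction == 1.0:
        return list(demo["participant_id"])
    rng = np.random.default_rng(seed)
    cells: dict[tuple, list[str]] = {}
    for pid, diag, sex in zip(demo["participant_id"], demo["diagnosis"], demo["sex"]):
        cells.setdefault((diag, sex), []).append(pid)
    keys = sorted(cells)
    target_total = int(round(fraction * len(demo)))
    exact = np.array([fraction * len(cells[k]) for k in keys])
    base = np.floor(exact).astype(int)
    remainder = exact - base
    short = target_total - int(base.sum())
    order = np.argsort(-remainder, kind="stable")
    for i in order[: max(short, 0)]:
        base[i] += 1
    selected: list[str] = []
    for k, quota in zip(keys, base):
        quota = min(int(quota), len(cells[k]))
        if quota == 0:
            warnings.warn(f"cell {k} quota is zero at fraction {fraction}; skipped")
            continue
        selected.extend(rng.choice(cells[k], size=quota, replace=False))
    return sorted(selected)


def supra_threshold_pattern(
    effects: pd.DataFrame, threshold: float = ETA2_THRESHOLD
) -> pd.Series:
    """Binary supra-threshold label per (variable, age group, term) cell.

    Failed fits (NaN eta²) are labelled sub-threshold.
    """
    idx = pd.MultiIndex.from_frame(effects[["variable", "age_group", "term"]])
    values = (effects["eta2"] > threshold).fillna(False).to_numpy()
    return pd.Series(values, index=idx, name="supra")


def nmi(a: np.ndarray, b: np.ndarray, normalization: str = "sum") -> float:
    """Normalized mutual information of two binary partitions of cells.

    Builds the 2x2 contingency table and normalizes I(A;B) by the sum form
    2I/(H(A)+H(B)) (alternatives: "sqrt", "max").  Degenerate cases: both
    partitions single-class and identical -> 1; exactly one single-class -> 0.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("patterns must have equal length")
    n = a.size
    table = np.array(
        [
            [np.count_nonzero(~a & ~b), np.count_nonzero(~a & b)],
            [np.count_nonzero(a & ~b), np.count_nonzero(a & b)],
        ],
        dtype=float,
    )
    pij = table / n
    pa = pij.sum(axis=1)
    pb = pij.sum(axis=0)

    def entropy(p: np.ndarray) -> float:
        nz = p[p > 0]
        return float(-np.sum(nz * np.log(nz)))

    ha, hb = entropy(pa), entropy(pb)
    if ha == 0 and hb == 0:
        return 1.0 if np.array_equal(a, b) else 0.0
    if ha == 0 or hb == 0:
        return 0.0
    mi = 0.0
    for i in range(2):
        for j in range(2):
            if pij[i, j] > 0:
                mi += pij[i, j] * np.log(pij[i, j] / (pa[i] * pb[j]))
    if normalization == "sum":
        return float(2 * mi / (ha + hb))
    if normalization == "sqrt":
        return float(mi / np.sqrt(ha * hb))
    if normalization == "max":
        return float(mi / max(ha, hb))
    raise ValueError(f"unknown normalization {normalization!r}")


def bootstrap_curve(
    features: pd.DataFrame,
    demographics: pd.DataFrame,
    grouping: AgeGrouping,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    reps: int = 100,
    seed: int = 0,
    threshold: float = ETA2_THRESHOLD,
    normalization: str = "sum",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeat the full effect sweep on stratified subsamples of each fraction.

    Subsamples are drawn within each age group (preserving diagnosis and
    sex proportions), the sweep is re-run, and two statistics extracted:
    per-term proportion of eta² > threshold per run, and per-term pairwise
    NMI of supra-threshold patterns across runs of the same fraction.

    Returns (run records, NMI records).
    """
    demo = demographics.set_index("participant_id")
    master = np.random.SeedSequence(seed)
    run_rows = []
    nmi_rows = []
    for fi, fraction in enumerate(fractions):
        patterns: dict[int, pd.Series] = {}
        frac_seeds = master.spawn(len(fractions))[fi].spawn(reps)
        for rep in range(reps):
            rng_seeds = frac_seeds[rep].spawn(len(AGE_GROUPS))
            ids: list[str] = []
            for g, group in enumerate(AGE_GROUPS):
                group_ids = [i for i in grouping.ids_in(group) if i in demo.index]
                if not group_ids:
                    continue
                sub = demo.loc[group_ids].reset_index()
                ids.extend(
                    subsample(sub, fraction, int(rng_seeds[g].generate_state(1)[0]))
                )
            sel_feat = features[features["participant_id"].isin(ids)]
            sel_demo = demographics[demographics["participant_id"].isin(ids)]
            try:
                eff = effect_table(sel_feat, sel_demo, grouping)
            except Exception as exc:  # noqa: BLE001 - run excluded, not fatal
                warnings.warn(f"run (fraction={fraction}, rep={rep}) failed: {exc}")
                continue
            pattern = supra_threshold_pattern(eff, threshold)
            patterns[rep] = pattern
            for term, sub_pattern in pattern.groupby(level="term"):
                run_rows.append(
                    {
                        "fraction": fraction,
                        "rep": rep,
                        "term": term,
                        "proportion": float(sub_pattern.mean()),
                        "n_selected": len(ids),
                    }
                )
        terms = sorted({t for p in patterns.values() for t in p.index.get_level_values("term").unique()})
        for r1, r2 in itertools.combinations(sorted(patterns), 2):
            for term in terms:
                p1 = patterns[r1].xs(term, level="term").to_numpy()
                p2 = patterns[r2].xs(term, level="term").to_numpy()
                nmi_rows.append(
                    {
                        "fraction": fraction,
                        "rep_a": r1,
                        "rep_b": r2,
                        "term": term,
                        "nmi": nmi(p1, p2, normalization),
                    }
                )
    return pd.DataFrame(run_rows), pd.DataFrame(nmi_rows)


def matched_sample(
    demographics: pd.DataFrame,
    age_tolerance: float = 5.0,
    iq_tolerance: float = 10.0,
) -> pd.DataFrame:
    """Greedy 1:1 demographic matching of autistic cases to CON controls.

    Cases (AD or ASD) are visited in ascending-age order (ties broken by
    participant id); each is matched to the unused CON participant of the
    same sex minimising |age difference|, subject to |age difference| <=
    age_tolerance months and |IQ difference| <= iq_tolerance points (ties:
    smaller |IQ difference|, then id).  Unmatched cases and unused controls
    are discarded.  Returns a (case_id, control_id) pair table.
    """
    cases = demographics[demographics["diagnosis"].isin(("AD", "ASD"))].copy()
    controls = demographics[demographics["diagnosis"] == "CON"].copy()
    cases = cases.sort_values(["age_months", "participant_id"], kind="mergesort")
    available = controls.set_index("participant_id")
    pairs = []
    for _, case in cases.iterrows():
        pool = available[available["sex"] == case["sex"]]
        if pool.empty:
            continue
        d_age = (pool["age_months"] - case["age_months"]).abs()
        d_iq = (pool["iq"] - case["iq"]).abs()
        eligible = pool[(d_age <= age_tolerance) & (d_iq <= iq_tolerance)]
        if eligible.empty:
            continue
        ranking = pd.DataFrame(
            {"d_age": d_age[eligible.index], "d_iq": d_iq[eligible.index]}
        ).sort_index()
        ranking = ranking.sort_values(["d_age", "d_iq"], kind="mergesort")
        control_id = ranking.index[0]
        pairs.append({"case_id": case["participant_id"], "control_id": control_id})
        available = available.drop(index=control_id)
    return pd.DataFrame(pairs, columns=["case_id", "control_id"])


def matched_ids(pairs: pd.DataFrame) -> list[str]:
    """All participant ids retained by a matched-sample pair table."""
    return list(pairs["case_id"]) + list(pairs["control_id"])
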