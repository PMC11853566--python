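"""Per-variable, per-age-group linear modelling with type-III partial eta².

For every dependent variable and age tertile the sweep removes extreme
outliers, decides whether a quadratic age term is warranted (likelihood
ratio test), fits four nested OLS models (main effects; + diagnosis x sex;
+ diagnosis x age; full age x sex x diagnosis factorial + IQ), and extracts
type-III partial eta² for the designated term of each model.

All fitting is plain least squares on explicitly constructed design
matrices with sum-to-zero contrasts, so type-III sums of squares are
obtained by drop-term residual comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

MODELS = ("M1", "M2", "M3", "M4")
AGE_GROUPS = ("youngest", "middle", "oldest")

#: Terms whose partial eta² is extracted, per model.
DESIGNATED_TERMS: dict[str, tuple[str, ...]] = {
    "M1": ("Age", "Sex", "IQ", "Diagnosis"),
    "M2": ("Diagnosis:Sex",),
    "M3": ("Diagnosis:Age",),
    "M4": ("Age:Sex:Diagnosis",),
}

DIAGNOSIS_LEVELS = ("AD", "ASD", "CON")
AUTISTIC = ("AD", "ASD")


@dataclass
class AgeGrouping:
    """Participant -> age tertile assignment plus the boundary ages."""

    labels: pd.Series  # participant_id -> {youngest, middle, oldest}
    boundaries: tuple[float, float]

    def ids_in(self, group: str) -> list[str]:
        return list(self.labels.index[self.labels == group])


def _even_split_sizes(n: int) -> list[int]:
    q, r = divmod(n, 3)
    return [q + (1 if i < r else 0) for i in range(3)]


def assign_age_tertiles(demographics: pd.DataFrame) -> AgeGrouping:
    """Split the cohort into three age groups balancing AD and ASD counts.

    AD participants are ranked by (age, participant_id) and split into three
    consecutive chunks with sizes differing by at most one; likewise ASD.
    CON participants are assigned by the age boundaries implied by the
    pooled autistic assignment.  Ties are broken by participant id, so the
    assignment is deterministic.
    """
    demo = demographics.set_index("participant_id")
    for diag in ("AD", "ASD"):
        if (demo["diagnosis"] == diag).sum() < 3:
            raise ValueError(f"need at least 3 {diag} participants")

    labels: dict[str, str] = {}
    for diag in ("AD", "ASD"):
        # stable sort on age after id sort => ordered by (age, participant_id)
        sub = demo[demo["diagnosis"] == diag].sort_index()
        sub = sub.sort_values("age_months", kind="mergesort")
        sizes = _even_split_sizes(len(sub))
        start = 0
        for group, size in zip(AGE_GROUPS, sizes):
            for pid in sub.index[start : start + size]:
                labels[pid] = group
            start += size

    autistic = demo[demo["diagnosis"].isin(AUTISTIC)]
    ages_by_group = {g: [] for g in AGE_GROUPS}
    for pid in autistic.index:
        ages_by_group[labels[pid]].append(float(autistic.loc[pid, "age_months"]))
    b1 = max(ages_by_group["youngest"]) if ages_by_group["youngest"] else -np.inf
    b2 = max(ages_by_group["middle"]) if ages_by_group["middle"] else b1

    for pid, row in demo[demo["diagnosis"] == "CON"].iterrows():
        a = float(row["age_months"])
        labels[pid] = "youngest" if a <= b1 else ("middle" if a <= b2 else "oldest")

    series = pd.Series(labels, name="age_group")
    series = series.loc[demo.index]  # original order
    return AgeGrouping(labels=series, boundaries=(float(b1), float(b2)))


def remove_outliers(
    values: np.ndarray,
    diagnosis: np.ndarray,
    z_threshold: float = 3.5,
) -> tuple[np.ndarray, dict[str, int]]:
    """Keep-mask for a robust-z outlier rule within one age group.

    A value is extreme when |value - median| > z_threshold * 1.4826 * MAD.
    Zero MAD (degenerate spread) removes nothing.  Removal counts are
    reported split by autistic (AD or ASD) vs neurotypical.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 values for outlier screening")
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        keep = np.ones(values.size, dtype=bool)
    else:
        keep = np.abs(values - med) <= z_threshold * 1.4826 * mad
    removed = ~keep
    diagnosis = np.asarray(diagnosis)
    counts = {
        "autistic": int(np.count_nonzero(removed & np.isin(diagnosis, AUTISTIC))),
        "neurotypical": int(np.count_nonzero(removed & (diagnosis == "CON"))),
    }
    return keep, counts


def _ols_rss(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, int]:
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), beta, int(rank)


def lrt_age_quadratic(
    values: np.ndarray, age: np.ndarray, alpha: float = 0.05
) -> tuple[bool, float, float]:
    """Likelihood-ratio test of value ~ Age vs value ~ Age + Age².

    LR = n * ln(RSS0 / RSS1), compared to chi²(1).  Returns
    (use_age2, LR statistic, p-value).
    """
    y = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 complete cases")
    a = age - age.mean()
    x0 = np.column_stack([np.ones(n), a])
    x1 = np.column_stack([np.ones(n), a, a**2 - (a**2).mean()])
    rss0, _, rank0 = _ols_rss(x0, y)
    rss1, _, rank1 = _ols_rss(x1, y)
    if rank1 < x1.shape[1]:
        return False, 0.0, 1.0
    eps = max(1e-12 * float(y @ y), 1e-300)
    if rss0 <= eps:
        return False, 0.0, 1.0
    if rss1 <= eps:
        return True, np.inf, 0.0
    lr = n * np.log(rss0 / rss1)
    p = float(sps.chi2.sf(lr, 1))
    return bool(p < alpha), float(lr), p


@dataclass
class ModelFit:
    """One OLS fit with term -> design-column bookkeeping for type-III tests."""

    model: str
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    term_cols: dict[str, list[int]]
    beta: np.ndarray = field(repr=False)
    rss: float
    rank: int

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def df_resid(self) -> int:
        return self.n - self.x.shape[1]

    @property
    def rank_deficient(self) -> bool:
        return self.rank < self.x.shape[1]


def _codes(demographics: pd.DataFrame) -> dict[str, np.ndarray]:
    age = demographics["age_months"].to_numpy(dtype=float)
    iq = demographics["iq"].to_numpy(dtype=float)
    sex = np.where(demographics["sex"].to_numpy() == "F", 1.0, -1.0)
    diag = demographics["diagnosis"].to_numpy()
    # sum-to-zero contrasts, CON as the implicit reference level
    d1 = np.where(diag == "AD", 1.0, np.where(diag == "CON", -1.0, 0.0))
    d2 = np.where(diag == "ASD", 1.0, np.where(diag == "CON", -1.0, 0.0))
    a = age - age.mean()
    return {
        "age": a,
        "age2": a**2 - (a**2).mean(),
        "sex": sex,
        "iq": iq - iq.mean(),
        "d1": d1,
        "d2": d2,
    }


def build_design(
    demographics: pd.DataFrame, model: str, use_age2: bool
) -> tuple[np.ndarray, dict[str, list[int]]]:
    """Design matrix and term -> column map for one of the four models.

    Continuous covariates are mean-centred within the supplied subset;
    Sex and Diagnosis carry sum-to-zero contrasts so drop-term residual
    comparisons yield type-III sums of squares.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    c = _codes(demographics)
    n = len(demographics)
    cols: list[np.ndarray] = [np.ones(n)]
    term_cols: dict[str, list[int]] = {}

    def add(term: str, arrays: list[np.ndarray]) -> None:
        idx = []
        for arr in arrays:
            idx.append(len(cols))
            cols.append(arr)
        term_cols[term] = idx

    add("Age", [c["age"]])
    if use_age2:
        add("Age2", [c["age2"]])
    add("Sex", [c["sex"]])
    add("IQ", [c["iq"]])
    add("Diagnosis", [c["d1"], c["d2"]])
    if model == "M2":
        add("Diagnosis:Sex", [c["d1"] * c["sex"], c["d2"] * c["sex"]])
    elif model == "M3":
        add("Diagnosis:Age", [c["d1"] * c["age"], c["d2"] * c["age"]])
    elif model == "M4":
        add("Age:Sex", [c["age"] * c["sex"]])
        add("Diagnosis:Age", [c["d1"] * c["age"], c["d2"] * c["age"]])
        add("Diagnosis:Sex", [c["d1"] * c["sex"], c["d2"] * c["sex"]])
        add("Age:Sex:Diagnosis", [c["d1"] * c["age"] * c["sex"], c["d2"] * c["age"] * c["sex"]])
    return np.column_stack(cols), term_cols


def fit_models(
    values: np.ndarray, demographics: pd.DataFrame, use_age2: bool
) -> dict[str, ModelFit]:
    """Fit M1-M4 by OLS on one variable's values within one age group."""
    y = np.asarray(values, dtype=float)
    fits = {}
    for model in MODELS:
        x, term_cols = build_design(demographics, model, use_age2)
        rss, beta, rank = _ols_rss(x, y)
        fits[model] = ModelFit(
            model=model, x=x, y=y, term_cols=term_cols, beta=beta, rss=rss, rank=rank
        )
    return fits


def partial_eta2_type3(fit: ModelFit, term: str) -> tuple[float, float]:
    """Type-III partial eta² and F-test p-value for one model term.

    SS_term = RSS(model without the term's columns) - RSS(full model);
    eta² = SS_term / (SS_term + RSS(full)).
    """
    if term not in fit.term_cols:
        raise ValueError(f"term {term!r} not in model {fit.model}")
    if fit.rank_deficient:
        return np.nan, np.nan
    drop = set(fit.term_cols[term])
    keep = [j for j in range(fit.x.shape[1]) if j not in drop]
    rss_reduced, _, _ = _ols_rss(fit.x[:, keep], fit.y)
    ss_term = max(rss_reduced - fit.rss, 0.0)
    denom = ss_term + fit.rss
    eta2 = ss_term / denom if denom > 0 else 0.0
    df_term = len(drop)
    df_res = fit.df_resid
    if fit.rss <= 0:
        p = 0.0 if ss_term > 0 else 1.0
    elif df_res <= 0:
        p = np.nan
    else:
        f_stat = (ss_term / df_term) / (fit.rss / df_res)
        p = float(sps.f.sf(f_stat, df_term, df_res))
    return float(eta2), p


def compute_gvif(fit: ModelFit) -> dict[str, float]:
    """Adjusted generalised VIF (GVIF^(1/(2 df))) per non-intercept term.

    Uses the determinant formulation on the correlation matrix of the
    design columns.  Raises on aliased (linearly dependent) columns.
    """
    cols = [j for j in range(fit.x.shape[1]) if any(j in v for v in fit.term_cols.values())]
    sub = fit.x[:, cols]
    sds = sub.std(axis=0, ddof=0)
    if np.any(sds == 0):
        raise ValueError("constant design column; cannot compute GVIF")
    r = np.corrcoef(sub, rowvar=False)
    det_r = np.linalg.det(r)
    pos = {j: i for i, j in enumerate(cols)}
    out = {}
    for term, idx in fit.term_cols.items():
        ti = [pos[j] for j in idx]
        oi = [i for i in range(len(cols)) if i not in ti]
        det_tt = np.linalg.det(r[np.ix_(ti, ti)]) if len(ti) > 1 else float(r[ti[0], ti[0]])
        det_oo = np.linalg.det(r[np.ix_(oi, oi)]) if oi else 1.0
        if det_r <= 1e-12:
            raise ValueError(f"aliased design columns (term {term!r})")
        gvif = det_tt * det_oo / det_r
        out[term] = float(gvif ** (1.0 / (2.0 * len(ti))))
    return out


def fit_term_eta2(
    values: np.ndarray,
    demographics: pd.DataFrame,
    model: str,
    term: str,
    use_age2: bool,
) -> tuple[float, float]:
    """Fit one model on one subset and return (eta², p) for one term."""
    x, term_cols = build_design(demographics, model, use_age2)
    rss, beta, rank = _ols_rss(x, np.asarray(values, dtype=float))
    fit = ModelFit(
        model=model, x=x, y=np.asarray(values, dtype=float),
        term_cols=term_cols, beta=beta, rss=rss, rank=rank,
    )
    return partial_eta2_type3(fit, term)


def effect_table(
    features: pd.DataFrame,
    demographics: pd.DataFrame,
    grouping: AgeGrouping,
    z_threshold: float = 3.5,
    lrt_alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the full sweep: outliers -> LRT -> M1-M4 -> designated-term eta².

    One output row per (variable, age group, model, designated term); four
    model fits per (variable, age group).  Per-variable failures are
    recorded in the ``error`` column and never abort the sweep.
    """
    demo = demographics.set_index("participant_id")
    variables = [c for c in features.columns if c != "participant_id"]
    feat = features.set_index("participant_id")
    records = []
    for age_group in AGE_GROUPS:
        ids = [pid for pid in grouping.ids_in(age_group) if pid in feat.index]
        sub_demo_all = demo.loc[ids]
        sub_feat = feat.loc[ids]
        for var in variables:
            y_all = sub_feat[var].to_numpy(dtype=float)
            complete = np.isfinite(y_all)
            y = y_all[complete]
            d = sub_demo_all[complete]
            base = {
                "variable": var,
                "age_group": age_group,
                "n_removed_autistic": 0,
                "n_removed_neurotypical": 0,
                "use_age2": False,
                "error": "",
            }
            try:
                keep, removed = remove_outliers(y, d["diagnosis"].to_numpy(), z_threshold)
                y = y[keep]
                d = d[keep]
                base["n_removed_autistic"] = removed["autistic"]
                base["n_removed_neurotypical"] = removed["neurotypical"]
                use_age2, _, _ = lrt_age_quadratic(
                    y, d["age_months"].to_numpy(), alpha=lrt_alpha
                )
                base["use_age2"] = use_age2
                fits = fit_models(y, d.reset_index(), use_age2)
                for model in MODELS:
                    for term in DESIGNATED_TERMS[model]:
                        eta2, p = partial_eta2_type3(fits[model], term)
                        records.append(
                            {
                                **base,
                                "model": model,
                                "term": term,
                                "eta2": eta2,
                                "p": p,
                                "n_used": int(y.size),
                            }
                        )
            except Exception as exc:  # noqa: BLE001 - sweep must not abort
                for model in MODELS:
                    for term in DESIGNATED_TERMS[model]:
                        records.append(
                            {
                                **base,
                                "model": model,
                                "term": term,
                                "eta2": np.nan,
                                "p": np.nan,
                                "n_used": 0,
                                "error": f"{type(exc).__name__}: {exc}",
                            }
                        )
    return pd.DataFrame.from_records(records)


def count_fits(effects: pd.DataFrame) -> int:
    """Number of distinct model fits underlying an effect table."""
    return len(effects[["variable", "age_group", "model"]].drop_duplicates())
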