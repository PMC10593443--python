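"""End-to-end screening analysis: cohort in, study-style tables out.

The central objects follow the model/results pattern:

* :class:`ScreeningAnalysis` — built from a cohort table
  (:meth:`~ScreeningAnalysis.from_csv` or
  :meth:`~ScreeningAnalysis.from_dataframe`); holds the included
  records, the exclusion log, and the analysis options.
* :class:`ScreeningResults` — returned by :meth:`ScreeningAnalysis.fit`;
  carries the component/MetS prevalences with CIs, per-sex
  mean-difference tables (each index split by each outcome, t-test),
  per-sex correlation tables (index vs quantitative component), per-sex
  AUC tables with CIs and significance, and per-sex optimal-cutoff
  tables; exposes ``summary()`` and ``save_tables()``.

Exclusion rule: a row missing any MetS-relevant field (sex, wc, sbp,
dbp, fbg, tg, hdl) is excluded with a logged reason; parsed =
included + excluded always holds. Other missing measurements leave the
affected index cells not-estimable rather than dropping the subject.

All computation is done at full precision; display rounding (2 decimals
for indices and AUCs, 1 for percentages) happens only at serialisation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .indices import INDEX_NAMES, CONICITY_K_DEFAULT, compute_indices_df
from .mets import COMPONENT_NAMES, ThresholdSet, classify_components_df
from .records import SEXES
from .roc import auc_inference, optimal_cutoff
from .stats import proportion_ci, pearson_corr, t_test, significance_star

__all__ = [
    "COHORT_COLUMNS",
    "ScreeningAnalysis",
    "ScreeningResults",
    "read_cohort_csv",
    "write_cohort_csv",
    "run_analysis",
]

#: CSV schema: column -> (dtype kind, unit, required for MetS classification)
COHORT_COLUMNS = {
    "id": ("str", "-", False),
    "sex": ("str", "male|female", True),
    "age": ("float", "years", False),
    "height": ("float", "cm", False),
    "weight": ("float", "kg", False),
    "wc": ("float", "cm", True),
    "nc": ("float", "cm", False),
    "muac": ("float", "cm", False),
    "sbp": ("float", "mmHg", True),
    "dbp": ("float", "mmHg", True),
    "fbg": ("float", "mg/dL", True),
    "tg": ("float", "mmol/L", True),
    "hdl": ("float", "mmol/L", True),
    "on_bp_meds": ("bool", "-", False),
    "on_lipid_meds": ("bool", "-", False),
    "on_glucose_meds": ("bool", "-", False),
}

_MANDATORY_HEADER = [c for c, (_, _, req) in COHORT_COLUMNS.items() if req]

#: outcome groupings analysed against every index (five components + MetS)
OUTCOME_NAMES = COMPONENT_NAMES + ["mets"]
#: quantitative MetS components for the correlation table
QUANT_COMPONENTS = ["sbp", "dbp", "fbg", "tg", "hdl"]


def read_cohort_csv(path) -> tuple[pd.DataFrame, list[dict]]:
    """Parse a cohort CSV into (included rows, exclusion log).

    Raises on a malformed header (missing mandatory columns) or an empty
    data section; rows with missing or unparseable MetS-relevant fields
    are excluded with per-row reasons. Row order is preserved.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing_cols = [c for c in _MANDATORY_HEADER if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"cohort CSV missing required columns: {missing_cols}")
    if len(raw) == 0:
        raise ValueError("cohort CSV has no data rows")
    unknown = [c for c in raw.columns if c not in COHORT_COLUMNS]
    if unknown:
        import warnings

        warnings.warn(f"ignoring unknown cohort columns: {unknown}", stacklevel=2)
        raw = raw.drop(columns=unknown)

    df = pd.DataFrame(index=raw.index)
    df["id"] = raw["id"] if "id" in raw.columns else [f"row{i}" for i in raw.index]
    df["sex"] = raw["sex"].str.strip().str.lower() if "sex" in raw.columns else None
    for col, (kind, _, _) in COHORT_COLUMNS.items():
        if col in ("id", "sex"):
            continue
        if col not in raw.columns:
            df[col] = False if kind == "bool" else np.nan
        elif kind == "bool":
            df[col] = (
                raw[col].str.strip().str.lower().map(
                    {"true": True, "1": True, "yes": True,
                     "false": False, "0": False, "no": False}
                ).fillna(False).astype(bool)
            )
        else:
            df[col] = pd.to_numeric(raw[col], errors="coerce")

    exclusions: list[dict] = []
    keep = np.ones(len(df), bool)
    for i in df.index:
        reasons = []
        if df.at[i, "sex"] not in SEXES:
            reasons.append("invalid sex")
        for col in _MANDATORY_HEADER:
            if col == "sex":
                continue
            if pd.isna(df.at[i, col]):
                reasons.append(f"missing {col}")
        if reasons:
            keep[i] = False
            exclusions.append({"id": df.at[i, "id"], "reason": "; ".join(reasons)})
    return df[keep].reset_index(drop=True), exclusions


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write a cohort table in the package's CSV dialect (UTF-8, header).

    Uses repr-round-trip float formatting so write-then-read is the
    identity on valid cohorts and regeneration is byte-identical.
    """
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False, lineterminator="\n")


@dataclass
class ScreeningResults:
    """Fitted screening analysis: study-style tables plus metadata.

    Attributes hold tidy DataFrames; ``summary()`` renders a compact
    text report and ``save_tables()`` writes one CSV per table.
    """

    cohort_summary: dict
    prevalence: pd.DataFrame
    mean_difference: pd.DataFrame
    correlations: pd.DataFrame
    auc_table: pd.DataFrame
    cutoff_table: pd.DataFrame
    exclusions: list
    options: dict
    notes: list = field(default_factory=list)

    def summary(self) -> str:
        cs = self.cohort_summary
        buf = io.StringIO()
        w = buf.write
        w("Anthropometric MetS screening analysis\n")
        w("=" * 54 + "\n")
        w(f"Included subjects: {cs['n_included']} "
          f"({cs['n_male']} male, {cs['n_female']} female); "
          f"excluded: {cs['n_excluded']}\n")
        w(f"Age: {cs['age_mean']:.2f} +/- {cs['age_sd']:.2f} years\n\n")
        w("Component and MetS prevalence (95% CI):\n")
        for _, r in self.prevalence.iterrows():
            w(f"  {r['group']:<22s} {100 * r['prevalence']:5.1f}% "
              f"({100 * r['ci_lower']:.1f}-{100 * r['ci_upper']:.1f})\n")
        w("\nAUC for predicting MetS (per sex):\n")
        sub = self.auc_table[self.auc_table["outcome"] == "mets"]
        for sex in SEXES:
            w(f"  {sex}:\n")
            for _, r in sub[sub["sex"] == sex].iterrows():
                if np.isnan(r["auc"]):
                    w(f"    {r['index']:<9s} not estimable\n")
                else:
                    w(f"    {r['index']:<9s} {r['auc']:.2f} "
                      f"({r['ci_lower']:.2f}-{r['ci_upper']:.2f})"
                      f"{r['star']}\n")
        w("\nOptimal cutoffs for MetS (Youden), per sex:\n")
        for sex in SEXES:
            w(f"  {sex}:\n")
            for _, r in self.cutoff_table[self.cutoff_table["sex"] == sex].iterrows():
                if np.isnan(r["cutoff"]):
                    w(f"    {r['index']:<9s} not estimable\n")
                else:
                    w(f"    {r['index']:<9s} cutoff {r['cutoff']:.2f}  "
                      f"sens {r['sensitivity']:.2f}  1-spec {r['one_minus_specificity']:.2f}\n")
        for note in self.notes:
            w(f"\nNote: {note}\n")
        return buf.getvalue()

    def save_tables(self, out_dir) -> list[Path]:
        """Write one tidy CSV per table into ``out_dir``; returns paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []

        def emit(name, df, float_cols_2dp=(), pct_cols=()):
            d = df.copy()
            for c in pct_cols:
                d[c] = (100 * d[c]).round(1)
            for c in float_cols_2dp:
                d[c] = d[c].round(2)
            p = out / f"{name}.csv"
            d.to_csv(p, index=False, lineterminator="\n")
            written.append(p)

        emit("prevalence", self.prevalence,
             pct_cols=("prevalence", "ci_lower", "ci_upper"))
        emit("mean_difference", self.mean_difference,
             float_cols_2dp=("mean_yes", "sd_yes", "mean_no", "sd_no", "t"))
        emit("correlations", self.correlations, float_cols_2dp=("r",))
        emit("auc", self.auc_table,
             float_cols_2dp=("auc", "se", "ci_lower", "ci_upper"))
        emit("cutoffs", self.cutoff_table,
             float_cols_2dp=("cutoff", "sensitivity", "one_minus_specificity", "youden_j"))
        excl = pd.DataFrame(self.exclusions, columns=["id", "reason"])
        p = out / "exclusions.csv"
        excl.to_csv(p, index=False, lineterminator="\n")
        written.append(p)
        meta = pd.DataFrame(
            [{"key": k, "value": v} for k, v in self.cohort_summary.items()]
            + [{"key": f"option:{k}", "value": v} for k, v in self.options.items()]
            + [{"key": "note", "value": n} for n in self.notes]
        )
        p = out / "metadata.csv"
        meta.to_csv(p, index=False, lineterminator="\n")
        written.append(p)
        return written


class ScreeningAnalysis:
    """Screening-analysis model over a cohort table.

    Parameters
    ----------
    data : DataFrame
        Cohort in the standard schema (see ``COHORT_COLUMNS``); rows are
        assumed already validated/included.
    exclusions : list of dict, optional
        Exclusion log produced while loading (kept for the report).
    thresholds : ThresholdSet, optional
    conicity_k : float
        Conicity normalising constant (default 0.109).
    strict_idf : bool
        Use the strict-IDF overall rule (central obesity mandatory).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        exclusions: Optional[list] = None,
        thresholds: Optional[ThresholdSet] = None,
        conicity_k: float = CONICITY_K_DEFAULT,
        strict_idf: bool = False,
    ):
        if len(data) < 2:
            raise ValueError("cohort too small: need at least 2 included subjects")
        self.data = data.reset_index(drop=True)
        self.exclusions = list(exclusions or [])
        self.thresholds = thresholds or ThresholdSet()
        self.conicity_k = conicity_k
        self.strict_idf = strict_idf

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ScreeningAnalysis":
        data, exclusions = read_cohort_csv(path)
        return cls(data, exclusions=exclusions, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ScreeningAnalysis":
        return cls(df.copy(), **kwargs)

    def fit(
        self,
        t_test_variant: str = "welch",
        ci_method: str = "wilson",
        auc_method: str = "delong",
        cutoff_criterion: str = "youden",
    ) -> ScreeningResults:
        """Run the full analysis and return a :class:`ScreeningResults`."""
        df = self.data
        indices = compute_indices_df(df, conicity_k=self.conicity_k)
        comps = classify_components_df(df, self.thresholds, strict_idf=self.strict_idf)
        male = df["sex"] == "male"

        cohort_summary = {
            "n_parsed": len(df) + len(self.exclusions),
            "n_included": len(df),
            "n_excluded": len(self.exclusions),
            "n_male": int(male.sum()),
            "n_female": int((~male).sum()),
            "age_mean": float(df["age"].mean()),
            "age_sd": float(df["age"].std(ddof=1)),
        }

        prev_rows = []
        for comp in OUTCOME_NAMES:
            ci = proportion_ci(int(comps[comp].sum()), len(comps), method=ci_method)
            prev_rows.append(
                {"group": comp, "count": int(comps[comp].sum()), "n": ci.n,
                 "prevalence": ci.p_hat, "ci_lower": ci.lower, "ci_upper": ci.upper,
                 "method": ci.method}
            )
        for sex in SEXES:
            mask = df["sex"] == sex
            if mask.sum() > 0:
                ci = proportion_ci(int(comps.loc[mask, "mets"].sum()), int(mask.sum()),
                                   method=ci_method)
                prev_rows.append(
                    {"group": f"mets_{sex}", "count": int(comps.loc[mask, 'mets'].sum()),
                     "n": ci.n, "prevalence": ci.p_hat, "ci_lower": ci.lower,
                     "ci_upper": ci.upper, "method": ci.method}
                )
        prevalence = pd.DataFrame(prev_rows)

        md_rows, corr_rows, auc_rows, cut_rows = [], [], [], []
        for sex in SEXES:
            mask = (df["sex"] == sex).to_numpy()
            for idx in INDEX_NAMES:
                vals = indices.loc[mask, idx].to_numpy(float)
                # mean-difference per outcome
                for outcome in OUTCOME_NAMES:
                    grp = comps.loc[mask, outcome].to_numpy(bool)
                    ok = ~np.isnan(vals)
                    yes, no = vals[grp & ok], vals[~grp & ok]
                    row = {"sex": sex, "outcome": outcome, "index": idx,
                           "n_yes": yes.size, "n_no": no.size,
                           "mean_yes": np.nan, "sd_yes": np.nan,
                           "mean_no": np.nan, "sd_no": np.nan,
                           "t": np.nan, "p": np.nan, "star": "", "note": ""}
                    if yes.size:
                        row["mean_yes"], row["sd_yes"] = yes.mean(), yes.std(ddof=1)
                    if no.size:
                        row["mean_no"], row["sd_no"] = no.mean(), no.std(ddof=1)
                    try:
                        tt = t_test(yes, no, variant=t_test_variant)
                        row.update(t=tt.t, p=tt.p, star=significance_star(tt.p))
                    except ValueError as e:
                        row["note"] = f"not estimable: {e}"
                    md_rows.append(row)
                # correlations with quantitative components
                for comp in QUANT_COMPONENTS:
                    y = df.loc[mask, comp].to_numpy(float)
                    ok = ~(np.isnan(vals) | np.isnan(y))
                    row = {"sex": sex, "component": comp, "index": idx,
                           "n": int(ok.sum()), "r": np.nan, "p": np.nan,
                           "star": "", "note": ""}
                    try:
                        cr = pearson_corr(vals[ok], y[ok])
                        row.update(r=cr.r, p=cr.p, star=significance_star(cr.p))
                    except ValueError as e:
                        row["note"] = f"not estimable: {e}"
                    corr_rows.append(row)
                # ROC per outcome
                for outcome in OUTCOME_NAMES:
                    labels = comps.loc[mask, outcome].to_numpy(bool)
                    ok = ~np.isnan(vals)
                    row = {"sex": sex, "outcome": outcome, "index": idx,
                           "auc": np.nan, "se": np.nan, "ci_lower": np.nan,
                           "ci_upper": np.nan, "p_vs_half": np.nan,
                           "star": "", "note": ""}
                    try:
                        asum = auc_inference(vals[ok], labels[ok], method=auc_method)
                        row.update(auc=asum.auc, se=asum.se, ci_lower=asum.ci_lower,
                                   ci_upper=asum.ci_upper, p_vs_half=asum.p_vs_half,
                                   star=significance_star(asum.p_vs_half))
                    except ValueError as e:
                        row["note"] = f"not estimable: {e}"
                    auc_rows.append(row)
                # optimal cutoff for MetS
                labels = comps.loc[mask, "mets"].to_numpy(bool)
                ok = ~np.isnan(vals)
                row = {"sex": sex, "index": idx, "cutoff": np.nan,
                       "sensitivity": np.nan, "one_minus_specificity": np.nan,
                       "youden_j": np.nan, "note": ""}
                try:
                    cr = optimal_cutoff(vals[ok], labels[ok], criterion=cutoff_criterion)
                    row.update(cutoff=cr.cutoff, sensitivity=cr.sensitivity,
                               one_minus_specificity=cr.one_minus_specificity,
                               youden_j=cr.youden_j)
                except ValueError as e:
                    row["note"] = f"not estimable: {e}"
                cut_rows.append(row)

        return ScreeningResults(
            cohort_summary=cohort_summary,
            prevalence=prevalence,
            mean_difference=pd.DataFrame(md_rows),
            correlations=pd.DataFrame(corr_rows),
            auc_table=pd.DataFrame(auc_rows),
            cutoff_table=pd.DataFrame(cut_rows),
            exclusions=self.exclusions,
            options={
                "t_test_variant": t_test_variant, "ci_method": ci_method,
                "auc_method": auc_method, "cutoff_criterion": cutoff_criterion,
                "conicity_k": self.conicity_k, "strict_idf": self.strict_idf,
            },
            notes=["No multiple-testing adjustment is applied; p-values are per-comparison."],
        )


def run_analysis(data: pd.DataFrame, exclusions: Optional[list] = None, **options) -> ScreeningResults:
    """Functional entry point: build the model and fit in one call.

    ``options`` are split between the :class:`ScreeningAnalysis`
    constructor (thresholds, conicity_k, strict_idf) and
    :meth:`~ScreeningAnalysis.fit`.
    """
    ctor = {k: options.pop(k) for k in ("thresholds", "conicity_k", "strict_idf") if k in options}
    model = ScreeningAnalysis(data, exclusions=exclusions, **ctor)
    return model.fit(**options)
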