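"""Structured statistical report: the full battery in analysis order.

Runs the gatekeeping checks (normality, sphericity, Levene) and the main
analyses (descriptives, mixed ANOVA, Bonferroni pairwise, Welch F +
Games-Howell, GEE) on a cohort table and collects them into one serialisable
object mirroring the five result tables of a masticatory-performance study:
descriptives, within-subject ANOVA, Bonferroni session contrasts,
Games-Howell consumption-group contrasts, and GEE coefficient estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as st
from .synth import validate_cohort


@dataclass
class StatsReport:
    descriptives: pd.DataFrame          # table 3 analogue
    anova_within: pd.DataFrame          # table 4 analogue
    anova_between: pd.DataFrame
    bonferroni: pd.DataFrame            # table 5 analogue
    games_howell: pd.DataFrame          # table 6 analogue
    gee: pd.DataFrame                   # table 7 analogue
    gee_scale: float
    normality: pd.DataFrame
    eta_sq_age_cgc: float
    sphericity: st.SphericityResult
    correction: str
    levene_F: float
    levene_p: float
    welch: dict
    notes: list[str] = field(default_factory=list)

    _TABLES = {
        "table3": "descriptives", "table4": "anova_within",
        "table5": "bonferroni", "table6": "games_howell", "table7": "gee",
    }

    def to_dir(self, out_dir: str | Path) -> None:
        """Write table3.csv ... table7.csv plus report.json (deterministic)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, attr in self._TABLES.items():
            getattr(self, attr).to_csv(out_dir / f"{name}.csv", index=False)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def to_dict(self) -> dict:
        sph = self.sphericity
        return {
            "eta_sq_age_cgc": self.eta_sq_age_cgc,
            "sphericity": {"W": sph.W, "chi2": sph.chi2, "df": sph.df, "p": sph.p,
                           "eps_gg": sph.eps_gg, "eps_hf": sph.eps_hf,
                           "eps_lower": sph.eps_lower},
            "correction": self.correction,
            "levene": {"F": self.levene_F, "p": self.levene_p},
            "welch": self.welch,
            "gee_scale": self.gee_scale,
            "normality": self.normality.to_dict(orient="records"),
            "anova_between": self.anova_between.to_dict(orient="records"),
            "tables": {k: getattr(self, attr).to_dict(orient="records")
                       for k, attr in self._TABLES.items()},
            "notes": self.notes,
        }


def build_report(cohort: pd.DataFrame, gee_correlation: str = "independent"
                 ) -> StatsReport:
    """Run the full battery on a valid cohort table.

    The analysis order and decision rules follow the standard chain: check
    normality per consumption/dental-status/sex grouping, quantify the
    age-consumption association (eta^2 on one row per subject), run the
    sphericity-corrected mixed ANOVA with Bonferroni session contrasts, then
    -- because Levene's test typically rejects homogeneity across the
    repeated-measure levels -- the heteroscedastic Welch F with Games-Howell
    pairwise contrasts on the measurement-level data, and finally the
    normal/identity GEE.
    """
    validate_cohort(cohort)
    notes = []

    subj = cohort.drop_duplicates("subject_id")
    eta = st.eta_squared(subj["age"].to_numpy(), subj["cgc"].to_numpy())
    normality = st.normality_battery(cohort, ["cgc", "dental_status", "sex"])

    anova = st.mixed_anova(cohort)
    notes.append(
        f"sphericity p={st.format_p(anova.sphericity.p)}; "
        f"eps_gg={anova.sphericity.eps_gg:.3f} -> correction: {anova.correction}")

    bonf = st.bonferroni_pairwise(cohort)
    lev_F, lev_p = st.levene(cohort["vhh"].to_numpy(), cohort["cgc"].to_numpy())
    w_F, w_df1, w_df2, w_p = st.welch_anova(cohort["vhh"].to_numpy(),
                                            cohort["cgc"].to_numpy())
    gh = st.games_howell(cohort["vhh"].to_numpy(), cohort["cgc"].to_numpy())
    gee = st.fit_gee(cohort, working_correlation=gee_correlation)
    if gee.dropped_terms:
        notes.append("GEE terms dropped (empty cells): " + ", ".join(gee.dropped_terms))

    return StatsReport(
        descriptives=st.descriptives(cohort),
        anova_within=anova.within, anova_between=anova.between,
        bonferroni=bonf, games_howell=gh,
        gee=gee.table, gee_scale=gee.scale,
        normality=normality, eta_sq_age_cgc=eta,
        sphericity=anova.sphericity, correction=anova.correction,
        levene_F=lev_F, levene_p=lev_p,
        welch={"F": w_F, "df1": w_df1, "df2": w_df2, "p": w_p},
        notes=notes,
    )
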