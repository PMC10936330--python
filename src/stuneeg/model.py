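"""Model/Results interface over the per-animal and cohort analyses.

`StunModel` fits the full per-animal chain (preprocess -> spectral ->
baseline normalisation -> classification) for one pre/post recording
pair; `CohortStudy` fits every animal of a cohort and the group-level
statistics (report tables, quasi log-link GLM per band, KS contrasts,
chi-squared on good-stun counts).  Both follow the familiar
model-object pattern: construct from data, call ``fit()``, inspect the
returned results object or print its ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .assess import AnimalAssessment, AssessmentConfig, assess_animal
from .io import read_recording
from .recording import EEGRecording
from .stats import (
    CohortTables,
    GLMFit,
    KSResult,
    fit_quasi_log_glm,
    ks_two_sample,
    summarize_cohort,
)
from .synth import CohortAnimal, CohortDesign, generate_cohort


class StunModel:
    """Per-animal stun-effectiveness model.

    Parameters
    ----------
    pre, post : the pre-stun and post-stun recordings of one animal.
    config : analysis parameters (epoching, bands, dB convention,
        classification threshold); defaults reproduce the standard chain.
    """

    def __init__(self, pre: EEGRecording, post: EEGRecording,
                 config: AssessmentConfig | None = None):
        if pre is None or post is None:
            raise ValueError("both pre-stun and post-stun recordings are required")
        self.pre = pre
        self.post = post
        self.config = config or AssessmentConfig()

    @classmethod
    def from_files(cls, pre_path, post_path, config: AssessmentConfig | None = None,
                   **overrides) -> "StunModel":
        pre = read_recording(pre_path, phase="pre-stun", **overrides)
        post = read_recording(post_path, phase="post-stun", **overrides)
        return cls(pre, post, config=config)

    def fit(self) -> "StunResults":
        return StunResults(self, assess_animal(self.pre, self.post, self.config))


@dataclass
class StunResults:
    """Fitted per-animal results: periods, dB series and the verdict."""

    model: StunModel
    assessment_bundle: AnimalAssessment

    @property
    def assessment(self):
        return self.assessment_bundle.assessment

    @property
    def periods(self):
        return self.assessment_bundle.periods

    @property
    def db_series(self):
        return self.assessment_bundle.db_series

    @property
    def baseline(self):
        return self.assessment_bundle.baseline

    def db_chart_data(self) -> pd.DataFrame:
        """Per-band dB change per epoch, long format (chart export)."""
        dbs = self.db_series
        rows = []
        for j, name in enumerate(dbs.band_names):
            for i, start in enumerate(dbs.starts):
                rows.append({"start": float(start), "band": name,
                             "db": float(dbs.db[i, j]), "clean": bool(dbs.clean[i])})
        for i, start in enumerate(dbs.starts):
            rows.append({"start": float(start), "band": "total",
                         "db": float(dbs.db_total[i]), "clean": bool(dbs.clean[i])})
        return pd.DataFrame(rows)

    def to_row(self) -> dict:
        """One TSV-ready summary row for this animal."""
        a = self.assessment
        b = self.assessment_bundle
        supp = a.suppression
        return {
            "animal": b.animal_id,
            "treatment": b.treatment,
            "sustained": a.sustained,
            "threshold": a.threshold,
            "nadir_s": a.nadir_time,
            "nadir_db": a.nadir_db,
            "duration_s": a.sustained_duration,
            "suppression_start_s": supp[0] if supp else np.nan,
            "suppression_end_s": supp[1] if supp else np.nan,
            "first_usable_s": a.first_usable_time,
        }

    def summary(self) -> str:
        a = self.assessment
        b = self.assessment_bundle
        lines = [
            f"Stun assessment: animal={b.animal_id} treatment={b.treatment}",
            f"  sustained change (> {a.min_duration:g} s): "
            f"{'YES (good stun)' if a.sustained else 'no'}"
            f"  [threshold {a.threshold:g} dB on pooled delta+theta]",
            f"  longest above-threshold run: {a.sustained_duration:.2f} s",
            f"  nadir: {a.nadir_time:.2f} s post-stun ({a.nadir_db:+.1f} dB total power)",
            f"  suppression: "
            + (f"{a.suppression[0]:.2f}-{a.suppression[1]:.2f} s" if a.suppression else "none"),
            f"  first usable epoch: {a.first_usable_time:.2f} s post-stun",
        ]
        for label, period in self.periods.items():
            pct = " ".join(f"{k}={v:.1f}%" for k, v in period.pct.items())
            lines.append(f"  {label}: {pct}")
        return "\n".join(lines)


@dataclass
class CohortInput:
    """One animal of a cohort: recordings plus optional ground truth."""

    animal_id: str
    treatment: str
    pre: EEGRecording
    post: EEGRecording
    quality: str | None = None          # ground truth when synthetic


class CohortStudy:
    """Cohort-level stun-effectiveness study.

    Construct from explicit recordings (`CohortInput` list), from a
    synthetic cohort design (:meth:`from_synthetic`), or from a manifest
    of recording files (:meth:`from_manifest`); then ``fit()``.
    """

    def __init__(self, animals: list[CohortInput],
                 config: AssessmentConfig | None = None):
        if not animals:
            raise ValueError("cohort is empty")
        self.animals = animals
        self.config = config or AssessmentConfig()

    @classmethod
    def from_synthetic(cls, design: CohortDesign | None = None,
                       master_seed: int | None = None,
                       config: AssessmentConfig | None = None) -> "CohortStudy":
        cohort = generate_cohort(design, master_seed=master_seed)
        inputs = [CohortInput(a.animal_id, a.treatment, a.pre, a.post, a.quality)
                  for a in cohort]
        study = cls(inputs, config=config)
        study.ground_truth = {a.animal_id: a for a in cohort}
        return study

    @classmethod
    def from_manifest(cls, manifest_path, config: AssessmentConfig | None = None
                      ) -> "CohortStudy":
        manifest_path = Path(manifest_path)
        table = pd.read_csv(manifest_path, sep="\t")
        required = {"animal", "treatment", "phase", "file"}
        if not required.issubset(table.columns):
            raise ValueError(f"manifest must have columns {sorted(required)}")
        inputs = []
        for animal, grp in table.groupby("animal", sort=False):
            recs = {}
            for _, row in grp.iterrows():
                path = manifest_path.parent / row["file"]
                if not path.exists():
                    raise FileNotFoundError(
                        f"manifest entry for animal {animal!r} references "
                        f"missing file: {path}"
                    )
                recs[row["phase"]] = read_recording(
                    path, phase=row["phase"], animal=str(animal),
                    treatment=row["treatment"],
                )
            for phase in ("pre-stun", "post-stun"):
                if phase not in recs:
                    raise ValueError(f"animal {animal!r}: missing {phase} recording")
            quality = grp["quality"].iloc[0] if "quality" in grp.columns else None
            inputs.append(CohortInput(str(animal), grp["treatment"].iloc[0],
                                      recs["pre-stun"], recs["post-stun"], quality))
        return cls(inputs, config=config)

    def fit(self, glm_bands: tuple[str, ...] | None = None,
            ks_contrasts: bool = True) -> "CohortResults":
        """Assess every animal, then fit the group statistics."""
        per_animal: dict[str, StunResults] = {}
        for item in self.animals:
            per_animal[item.animal_id] = StunModel(item.pre, item.post,
                                                   self.config).fit()
        period_rows, db_rows, assessments = _long_tables(self.animals, per_animal)
        tables = summarize_cohort(period_rows, db_rows, assessments,
                                  threshold=self.config.threshold)
        glm_fits: dict[str, GLMFit] = {}
        band_names = glm_bands if glm_bands is not None else tuple(
            sorted(period_rows["band"].unique())
        )
        for band in band_names:
            sub = period_rows[(period_rows["band"] == band) & (period_rows["rms"] > 0)]
            sub = sub.rename(columns={"rms": "value"})
            if sub["treatment"].nunique() >= 2 and sub["period"].nunique() >= 2:
                glm_fits[band] = fit_quasi_log_glm(sub)
        ks = _ks_contrasts(self.animals, per_animal) if ks_contrasts else {}
        return CohortResults(self, per_animal, period_rows, db_rows, assessments,
                             tables, glm_fits, ks)


def _long_tables(animals, per_animal):
    period_rows, db_rows, assess_rows = [], [], []
    for item in animals:
        res = per_animal[item.animal_id]
        bundle = res.assessment_bundle
        for label, period in bundle.periods.items():
            for band in period.rms:
                period_rows.append({
                    "animal": item.animal_id, "treatment": item.treatment,
                    "period": label, "band": band,
                    "rms": period.rms[band], "pct": period.pct[band],
                })
        for label, dbvals in bundle.db_periods.items():
            for band, v in dbvals.items():
                db_rows.append({
                    "animal": item.animal_id, "treatment": item.treatment,
                    "period": label, "band": band, "db": v,
                })
        row = res.to_row()
        if item.quality is not None:
            row["quality"] = item.quality
        assess_rows.append(row)
    return (pd.DataFrame(period_rows), pd.DataFrame(db_rows),
            pd.DataFrame(assess_rows))


def _ks_contrasts(animals, per_animal) -> dict[tuple, KSResult]:
    """Pairwise treatment KS contrasts on epoch-level dB values, per period
    window and band (the distribution-level post hoc comparisons)."""
    treatments = sorted({a.treatment for a in animals})
    out: dict[tuple, KSResult] = {}
    pooled: dict[tuple, list] = {}
    for item in animals:
        dbs = per_animal[item.animal_id].db_series
        for label, (w0, w1) in (("T1", (0.0, 25.0)), ("T2", (26.0, 50.0))):
            sel = (dbs.starts >= w0) & (dbs.starts + dbs.epoch_length <= w1) & dbs.usable
            for j, band in enumerate(dbs.band_names):
                vals = dbs.db[sel, j]
                pooled.setdefault((item.treatment, label, band), []).extend(
                    vals[np.isfinite(vals)].tolist()
                )
    for (t1, t2) in combinations(treatments, 2):
        for label in ("T1", "T2"):
            bands = {k[2] for k in pooled if k[0] in (t1, t2) and k[1] == label}
            for band in sorted(bands):
                a = pooled.get((t1, label, band), [])
                b = pooled.get((t2, label, band), [])
                if len(a) >= 2 and len(b) >= 2:
                    out[(t1, t2, label, band)] = ks_two_sample(a, b)
    return out


@dataclass
class CohortResults:
    """Fitted cohort: per-animal results, report tables, GLM and KS output."""

    study: CohortStudy
    per_animal: dict[str, StunResults]
    period_rows: pd.DataFrame
    db_rows: pd.DataFrame
    assessments: pd.DataFrame
    tables: CohortTables
    glm_fits: dict[str, GLMFit]
    ks: dict[tuple, KSResult] = field(default_factory=dict)

    @property
    def ranking(self) -> list[str]:
        return self.tables.ranking

    def classification_accuracy(self) -> dict[str, float] | None:
        """Sensitivity/specificity against ground truth, when available."""
        if "quality" not in self.assessments.columns:
            return None
        df = self.assessments
        good = df["quality"] == "good"
        out = {}
        if good.any():
            out["sensitivity"] = float(df.loc[good, "sustained"].mean())
        if (~good).any():
            out["specificity"] = float((~df.loc[~good, "sustained"]).mean())
        return out

    def summary(self) -> str:
        t = self.tables
        lines = [f"Cohort study: {len(self.per_animal)} animals, "
                 f"threshold {t.threshold:g} dB"]
        lines.append("\nGood-stun counts (sustained > 25 s change):")
        lines.append(t.counts.to_string(index=False))
        if t.chi2 is not None:
            lines.append(
                f"chi2 = {t.chi2.statistic:.3f}, df = {t.chi2.df}, "
                f"p = {t.chi2.pvalue:.4f}"
                + ("  [warning: expected count < 5]" if t.chi2.small_expected else "")
            )
        lines.append("Ranking by good-stun proportion: " + " > ".join(t.ranking))
        acc = self.classification_accuracy()
        if acc:
            lines.append("Against ground truth: "
                         + ", ".join(f"{k}={v:.3f}" for k, v in acc.items()))
        lines.append("\nMean dB change from baseline (T1), by treatment and band:")
        sub = t.db_change[t.db_change["period"] == "T1"]
        pivot = sub.pivot_table(index="treatment", columns="band", values="mean")
        lines.append(pivot.round(1).to_string())
        return "\n".join(lines)
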