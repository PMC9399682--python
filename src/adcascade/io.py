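"""CSV schemas, feature naming, and run configuration.

Three tabular schemas flow through the pipeline:

* features CSV — long format, one row per subject x visit:
  ``subject_id, visit, <feature columns>``.  With the default d = 592 the
  feature columns are named ``{lh|rh}_{structure}_{CTh|FD|GI|SD}`` over the
  74 Destrieux (aparc.a2009s) structures per hemisphere and the four
  cortical geometric properties (cortical thickness, fractal dimension,
  gyrification index, sulcus depth).
* MMSE CSV — ``subject_id, visit, mmse``.
* clinical CSV — baseline covariates and the 4-class diagnosis:
  ``subject_id, age, sex, education_years, married, apoe4, cdr, faq,
  mmse, label`` with label in {NC, EMCI, LMCI, AD}; empty cells are
  missing (allowed everywhere except subject_id and label).

Binary covariates (sex = male, married, apoe4 = e4 carrier) are 0/1
indicators stored as numbers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import tglasso

__all__ = [
    "SchemaError",
    "DESTRIEUX_74",
    "PROPERTIES",
    "CLINICAL_COLUMNS",
    "VALID_LABELS",
    "feature_names",
    "read_features_csv",
    "write_features_csv",
    "read_mmse_csv",
    "write_mmse_csv",
    "read_clinical_csv",
    "write_clinical_csv",
    "build_design",
    "cohort_to_csvs",
    "write_weights_csv",
    "read_weights_csv",
    "RunConfig",
    "config_hash",
]


class SchemaError(ValueError):
    """A table does not match its declared schema; message carries coordinates."""


# FreeSurfer aparc.a2009s short names, 74 structures per hemisphere.
DESTRIEUX_74 = [
    "G_and_S_frontomargin", "G_and_S_occipital_inf", "G_and_S_paracentral",
    "G_and_S_subcentral", "G_and_S_transv_frontopol", "G_and_S_cingul-Ant",
    "G_and_S_cingul-Mid-Ant", "G_and_S_cingul-Mid-Post", "G_cingul-Post-dorsal",
    "G_cingul-Post-ventral", "G_cuneus", "G_front_inf-Opercular",
    "G_front_inf-Orbital", "G_front_inf-Triangul", "G_front_middle",
    "G_front_sup", "G_Ins_lg_and_S_cent_ins", "G_insular_short",
    "G_occipital_middle", "G_occipital_sup", "G_oc-temp_lat-fusifor",
    "G_oc-temp_med-Lingual", "G_oc-temp_med-Parahip", "G_orbital",
    "G_pariet_inf-Angular", "G_pariet_inf-Supramar", "G_parietal_sup",
    "G_postcentral", "G_precentral", "G_precuneus", "G_rectus",
    "G_subcallosal", "G_temp_sup-G_T_transv", "G_temp_sup-Lateral",
    "G_temp_sup-Plan_polar", "G_temp_sup-Plan_tempo", "G_temporal_inf",
    "G_temporal_middle", "Lat_Fis-ant-Horizont", "Lat_Fis-ant-Vertical",
    "Lat_Fis-post", "Pole_occipital", "Pole_temporal", "S_calcarine",
    "S_central", "S_cingul-Marginalis", "S_circular_insula_ant",
    "S_circular_insula_inf", "S_circular_insula_sup", "S_collat_transv_ant",
    "S_collat_transv_post", "S_front_inf", "S_front_middle", "S_front_sup",
    "S_interm_prim-Jensen", "S_intrapariet_and_P_trans",
    "S_oc_middle_and_Lunatus", "S_oc_sup_and_transversal", "S_occipital_ant",
    "S_oc-temp_lat", "S_oc-temp_med_and_Lingual", "S_orbital_lateral",
    "S_orbital_med-olfact", "S_orbital-H_Shaped", "S_parieto_occipital",
    "S_pericallosal", "S_postcentral", "S_precentral-inf-part",
    "S_precentral-sup-part", "S_suborbital", "S_subparietal",
    "S_temporal_inf", "S_temporal_sup", "S_temporal_transverse",
]

PROPERTIES = ("CTh", "FD", "GI", "SD")

CLINICAL_COLUMNS = ["age", "sex", "education_years", "married", "apoe4", "cdr", "faq", "mmse"]
VALID_LABELS = ("NC", "EMCI", "LMCI", "AD")


def feature_names(d: int) -> list[str]:
    """Column names for ``d`` imaging features.

    d = 592 yields the full atlas naming (2 hemispheres x 74 structures x 4
    properties, hemisphere-major order); other d get generic names.
    """
    if d == 2 * len(DESTRIEUX_74) * len(PROPERTIES):
        return [
            f"{hemi}_{name}_{prop}"
            for hemi in ("lh", "rh")
            for name in DESTRIEUX_74
            for prop in PROPERTIES
        ]
    return [f"feat_{i + 1:04d}" for i in range(d)]


_RESERVED = {"subject_id", "visit", "mmse", "label"}


def read_features_csv(path) -> pd.DataFrame:
    """Read and validate the long-format features table."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("subject_id", "visit"):
        if col not in df.columns:
            raise SchemaError(f"features CSV missing required column {col!r}")
    dup = df.duplicated(subset=["subject_id", "visit"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise SchemaError(
            f"duplicate (subject, visit) pair ({row['subject_id']!r}, {row['visit']!r})"
        )
    feat_cols = [c for c in df.columns if c not in _RESERVED]
    if not feat_cols:
        raise SchemaError("features CSV has no feature columns")
    for col in feat_cols:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            where = f" (first bad row index {bad.index[0]})" if len(bad) else ""
            raise SchemaError(f"non-numeric cell(s) in feature column {col!r}{where}")
    visits = sorted(df["visit"].unique())
    counts = df.groupby("subject_id")["visit"].apply(lambda v: sorted(v) != visits)
    if counts.any():
        sid = counts[counts].index[0]
        raise SchemaError(f"subject {sid!r} is missing one or more visits {visits}")
    return df


def write_features_csv(path, features: pd.DataFrame) -> None:
    features.to_csv(path, index=False, float_format="%.17g")


def read_mmse_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("subject_id", "visit", "mmse"):
        if col not in df.columns:
            raise SchemaError(f"MMSE CSV missing required column {col!r}")
    if not pd.api.types.is_numeric_dtype(df["mmse"]):
        raise SchemaError("non-numeric cell(s) in column 'mmse'")
    return df


def write_mmse_csv(path, mmse: pd.DataFrame) -> None:
    mmse.to_csv(path, index=False, float_format="%.17g")


def read_clinical_csv(path) -> pd.DataFrame:
    """Read and validate the baseline clinical table."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["subject_id", *CLINICAL_COLUMNS, "label"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"clinical CSV missing required column {col!r}")
    if df["label"].isna().any():
        idx = df.index[df["label"].isna()][0]
        raise SchemaError(f"missing label at row {idx}")
    bad = ~df["label"].isin(VALID_LABELS)
    if bad.any():
        lev = df.loc[bad.idxmax(), "label"]
        raise SchemaError(
            f"unknown label level {lev!r}; allowed labels are {', '.join(VALID_LABELS)}"
        )
    for col in CLINICAL_COLUMNS:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise SchemaError(f"non-numeric cell(s) in clinical column {col!r}")
        df[col] = df[col].astype(float)
    return df


def write_clinical_csv(path, clinical: pd.DataFrame) -> None:
    clinical.to_csv(path, index=False, float_format="%.17g")


def build_design(features: pd.DataFrame, mmse: pd.DataFrame):
    """Assemble a LongitudinalDesign from the two long-format tables.

    Rows are subject-aligned across visits (required by the
    output-smoothness penalty).  Returns (design, subject_ids, feature_ids).
    """
    feat_cols = [c for c in features.columns if c not in _RESERVED]
    visits = sorted(features["visit"].unique())
    subjects = list(dict.fromkeys(features["subject_id"]))
    merged = features.merge(mmse, on=["subject_id", "visit"], how="left")
    if merged["mmse"].isna().any():
        row = merged.loc[merged["mmse"].isna().idxmax()]
        raise SchemaError(
            f"no MMSE value for subject {row['subject_id']!r} visit {row['visit']!r}"
        )
    X, y = [], []
    for v in visits:
        sub = merged[merged["visit"] == v].set_index("subject_id").loc[subjects]
        X.append(sub[feat_cols].to_numpy(dtype=float))
        y.append(sub["mmse"].to_numpy(dtype=float))
    return tglasso.LongitudinalDesign(X, y), subjects, feat_cols


def cohort_to_csvs(cohort, out_dir) -> dict[str, Path]:
    """Write a synthetic cohort's three tables; returns the file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for j in range(cohort.design.T):
        df = pd.DataFrame(cohort.design.X[j], columns=cohort.feature_ids)
        df.insert(0, "visit", j + 1)
        df.insert(0, "subject_id", cohort.subject_ids)
        frames.append(df)
    features = pd.concat(frames, ignore_index=True)
    paths = {
        "features": out_dir / "features.csv",
        "mmse": out_dir / "mmse.csv",
        "clinical": out_dir / "clinical.csv",
    }
    write_features_csv(paths["features"], features)
    write_mmse_csv(paths["mmse"], cohort.mmse_long())
    write_clinical_csv(paths["clinical"], cohort.clinical_table)
    return paths


def write_weights_csv(path, W: np.ndarray, feature_ids: list[str]) -> None:
    """Fitted weight matrix as feature_id, w_t1..w_tT."""
    W = np.asarray(W)
    cols = {f"w_t{j + 1}": W[:, j] for j in range(W.shape[1])}
    pd.DataFrame({"feature_id": feature_ids, **cols}).to_csv(path, index=False, float_format="%.17g")


def read_weights_csv(path):
    df = pd.read_csv(path, float_precision="round_trip")
    wcols = [c for c in df.columns if c.startswith("w_t")]
    return df["feature_id"].tolist(), df[wcols].to_numpy(dtype=float)


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run; defaults are the
    study settings (penalties 0.25 / 0.08 / 0.04, SMOTE k = 10, 10 folds)."""

    lambda1: float = 0.25
    lambda2: float = 0.08
    lambda3: float = 0.04
    smote_k: int = 10
    folds: int = 10
    scenario: str = "AD-LMCI-NC-EMCI"
    learner: str = "adaboost"
    variant: str = "clinical+imaging"
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of a configuration (canonical JSON, sha256)."""
    payload = json.dumps(asdict(config), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
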