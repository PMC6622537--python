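"""Reading, writing, filtering and model persistence.

CSV schemas
-----------
* panel:        header = gene ids, first column = cell-line id, cells in {0,1,NA}
* drugs:        columns drug_id, smiles (optional), fp_0001..fp_NNNN (optional)
* sensitivity:  columns drug_id, cell_line_id, log10_ic50 (empty = missing)

All round trips are lossless; numeric fields are written with enough digits
to survive a write -> read cycle bit-for-bit at 10+ significant digits.

The dataset-level filter drops every cell line whose mutation status is
missing for 20 or more panel genes, codes the remaining sporadic missing
statuses as 0 (absence of evidence of mutation), and keeps only sensitivity
records with an observed IC50 that reference a retained cell line.
"""

from __future__ import annotations

import hashlib

import joblib
import numpy as np
import pandas as pd

from . import __version__
from .datatypes import DrugLibrary, FeatureMatrix, OncogenePanel, SensitivityTable
from .exceptions import FormatError, ReferentialIntegrityError, ValidationError

#: A cell line is dropped when at least this many genes have missing status.
MISSING_GENE_LIMIT = 20

_FLOAT_FMT = "%.12g"


def read_panel(path) -> OncogenePanel:
    """Read a cell line x gene mutation matrix from CSV."""
    try:
        df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse panel CSV {path}: {exc}") from exc
    raw = df.to_numpy(dtype=str)
    raw = np.char.strip(raw)
    out = np.full(raw.shape, np.nan)
    missing = np.isin(raw, ("", "NA", "NaN", "nan"))
    zeros = np.isin(raw, ("0", "0.0"))
    ones = np.isin(raw, ("1", "1.0"))
    bad = ~(missing | zeros | ones)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"panel {path}: invalid value {raw[i, j]!r} at row "
            f"{df.index[i]!r}, column {df.columns[j]!r} (expected 0, 1 or NA)"
        )
    out[zeros] = 0.0
    out[ones] = 1.0
    frame = pd.DataFrame(out, index=df.index.rename(None), columns=df.columns)
    return OncogenePanel(frame)


def write_panel(panel: OncogenePanel, path) -> None:
    df = panel.mutation.copy()
    # keep integers as 0/1 tokens so the round trip is exact
    df = df.map(lambda v: "" if np.isnan(v) else str(int(v)))
    df.to_csv(path, index_label="cell_line_id")


def read_drugs(path, n_continuous: int | None = None) -> DrugLibrary:
    """Read a drug table (drug_id, smiles[, fp_0001..]) from CSV."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse drug CSV {path}: {exc}") from exc
    if "drug_id" not in df.columns:
        raise FormatError(f"drug CSV {path} lacks a drug_id column")
    df = df.set_index("drug_id")
    df.index = df.index.rename(None)
    _reject_duplicates(df.index, "drug ids")
    smiles = df["smiles"].astype(str) if "smiles" in df.columns else None
    fp_cols = [c for c in df.columns if c.split("_")[0] in ("fp", "desc", "bit")]
    if fp_cols:
        fp = df[fp_cols].astype(float)
        if n_continuous is None:
            n_desc = sum(c.startswith("desc_") for c in fp_cols)
            if n_desc:
                n_continuous = n_desc
            else:
                from .datatypes import N_CONTINUOUS

                n_continuous = min(N_CONTINUOUS, len(fp_cols))
        return DrugLibrary(fingerprints=fp, smiles=smiles, n_continuous=n_continuous)
    if smiles is None:
        raise FormatError(f"drug CSV {path} has neither smiles nor fp_ columns")
    from .features import fingerprint_library

    return fingerprint_library(smiles)


def write_drugs(drugs: DrugLibrary, path) -> None:
    df = drugs.fingerprints.copy()
    if drugs.smiles is not None:
        df.insert(0, "smiles", drugs.smiles)
    df.to_csv(path, index_label="drug_id", float_format=_FLOAT_FMT)


def read_sensitivity(path) -> SensitivityTable:
    """Read long-form (drug_id, cell_line_id, log10_ic50) records from CSV."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse sensitivity CSV {path}: {exc}") from exc
    needed = {"drug_id", "cell_line_id", "log10_ic50"}
    if not needed <= set(df.columns):
        raise FormatError(f"sensitivity CSV {path} lacks columns {sorted(needed - set(df.columns))}")
    vals = pd.to_numeric(df["log10_ic50"], errors="coerce")
    bad = vals.isna() & df["log10_ic50"].notna() & (df["log10_ic50"].astype(str).str.strip() != "")
    if bad.any():
        raise FormatError(
            f"sensitivity CSV {path}: non-numeric log10_ic50 {df.loc[bad.idxmax(), 'log10_ic50']!r}"
        )
    rec = pd.DataFrame(
        {
            "drug_id": df["drug_id"],
            "cell_line_id": df["cell_line_id"],
            "log10_ic50": vals,
            "observed": vals.notna(),
        }
    )
    return SensitivityTable(rec)


def write_sensitivity(sens: SensitivityTable, path) -> None:
    df = sens.records[["drug_id", "cell_line_id", "log10_ic50"]].copy()
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def check_references(
    panel: OncogenePanel, drugs: DrugLibrary, sens: SensitivityTable
) -> None:
    """Raise unless every sensitivity record references known drug/cell ids."""
    unknown_drugs = set(sens.records["drug_id"]) - set(drugs.drug_ids)
    if unknown_drugs:
        raise ReferentialIntegrityError(f"unknown drug ids in sensitivity table: {sorted(unknown_drugs)[:5]}")
    unknown_cells = set(sens.records["cell_line_id"]) - set(panel.cell_line_ids)
    if unknown_cells:
        raise ReferentialIntegrityError(
            f"unknown cell line ids in sensitivity table: {sorted(unknown_cells)[:5]}"
        )


def filter_dataset(
    panel: OncogenePanel, sens: SensitivityTable
) -> tuple[OncogenePanel, SensitivityTable]:
    """Apply the dataset-level filtering rules.

    Drops cell lines with >= ``MISSING_GENE_LIMIT`` missing gene statuses,
    codes remaining missing statuses as 0, drops unobserved sensitivity
    records and records referencing dropped cell lines. Idempotent; never
    alters a retained numeric value.
    """
    keep = panel.missing_per_cell() < MISSING_GENE_LIMIT
    kept_cells = panel.cell_line_ids[keep]
    mut = panel.mutation.loc[kept_cells].fillna(0.0)
    rec = sens.records
    mask = rec["observed"] & rec["cell_line_id"].isin(set(kept_cells))
    rec = rec.loc[mask].reset_index(drop=True)
    if len(kept_cells) == 0 or len(rec) == 0:
        raise ValidationError("no data remain after filtering")
    return OncogenePanel(mut), SensitivityTable(rec)


def write_matrix(matrix: FeatureMatrix, path) -> None:
    matrix.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_matrix(path, n_genes: int | None = None) -> FeatureMatrix:
    """Read a serialized feature matrix; gene columns are those before the
    first fingerprint (``desc_``/``bit_``/``fp_``) column unless ``n_genes``
    is given."""
    df = pd.read_csv(path)
    meta = [c for c in ("drug_id", "cell_line_id", "label", "target") if c in df.columns]
    feat_cols = [c for c in df.columns if c not in meta]
    if n_genes is None:
        chem_start = next(
            (i for i, c in enumerate(feat_cols) if c.split("_")[0] in ("desc", "bit", "fp")),
            len(feat_cols),
        )
    else:
        chem_start = n_genes
    mode = "classify" if "label" in df.columns else "regress"
    return FeatureMatrix(
        ids=df[["drug_id", "cell_line_id"]],
        features=df[feat_cols].astype(float),
        gene_cols=feat_cols[:chem_start],
        chem_cols=feat_cols[chem_start:],
        label=df["label"].astype(int) if "label" in df.columns else None,
        target=df["target"].astype(float) if "target" in df.columns else None,
        mode=mode,
    )


def _schema_hash(obj_meta: dict) -> str:
    blob = repr(sorted(obj_meta.items())).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_model(model, path, meta: dict | None = None) -> None:
    """Persist a fitted model as a versioned blob with an embedded schema hash."""
    meta = dict(meta or {})
    meta["oncoforest_version"] = __version__
    payload = {"meta": meta, "schema_hash": _schema_hash(meta), "model": model}
    joblib.dump(payload, path)


def load_model(path):
    """Load a model blob; refuse cross-version or corrupted payloads loudly."""
    payload = joblib.load(path)
    if not isinstance(payload, dict) or {"meta", "schema_hash", "model"} - set(payload):
        raise FormatError(f"{path} is not an oncoforest model blob")
    meta = payload["meta"]
    if payload["schema_hash"] != _schema_hash(meta):
        raise FormatError(f"{path}: schema hash mismatch (corrupted blob)")
    if meta.get("oncoforest_version") != __version__:
        raise FormatError(
            f"{path}: model written by oncoforest {meta.get('oncoforest_version')}, "
            f"refusing to load into {__version__}"
        )
    return payload["model"], meta


def _reject_duplicates(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        raise ValidationError(f"duplicate {what}: {index[index.duplicated()].unique().tolist()[:5]}")
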