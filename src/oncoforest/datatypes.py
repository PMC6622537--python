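"""Core in-memory containers for the drug-sensitivity pipeline.

All containers wrap pandas objects and validate their domain invariants on
construction:

* :class:`OncogenePanel` — cell line x gene binary mutation matrix, the
  cellular half of every feature vector.
* :class:`DrugLibrary` — drug identifiers, optional SMILES, and fixed-length
  chemical fingerprints (192 continuous descriptors + 1024 circular
  fingerprint bits by default), the chemical half of every feature vector.
* :class:`SensitivityTable` — long-form (drug, cell line, log10 IC50 in molar,
  observed flag) records; the source of activity labels and regression
  targets.
* :class:`FeatureMatrix` — assembled per-pair rows with a class label and/or
  a continuous target plus the concatenated gene + chemistry features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: Default fingerprint layout: 192 continuous descriptors then 1024 bits.
N_CONTINUOUS = 192
N_BITS = 1024
FINGERPRINT_LENGTH = N_CONTINUOUS + N_BITS

#: Observed log10(IC50 / M) range of the screening panel being emulated,
#: from 5e-11 M (most sensitive) to 0.4 M (least sensitive combination).
LOG10_IC50_MIN = -10.3
LOG10_IC50_MAX = -0.4


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class OncogenePanel:
    """Binary mutation matrix over cell lines (rows) and genes (columns).

    ``mutation`` holds floats: 0.0, 1.0 or NaN (missing status). A value of 1
    means the gene carries any sequence variation in that cell line.
    """

    mutation: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.mutation
        _check_unique(m.index, "cell line ids")
        _check_unique(m.columns, "gene ids")
        vals = m.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValidationError(
                f"mutation entry for cell line {m.index[i]!r}, gene "
                f"{m.columns[j]!r} is {vals[i, j]!r}; must be 0, 1 or missing"
            )
        self.mutation = m.astype(float)

    @property
    def cell_line_ids(self) -> pd.Index:
        return self.mutation.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.mutation.columns

    @property
    def n_cells(self) -> int:
        return self.mutation.shape[0]

    @property
    def n_genes(self) -> int:
        return self.mutation.shape[1]

    def missing_per_cell(self) -> pd.Series:
        """Number of genes with missing mutation status, per cell line."""
        return self.mutation.isna().sum(axis=1)

    def mutated_fraction(self) -> pd.Series:
        """Per-gene fraction of cell lines carrying a mutation (NaN-ignoring)."""
        return self.mutation.mean(axis=0, skipna=True)


@dataclass
class DrugLibrary:
    """Drug identifiers with SMILES (optional) and chemical fingerprints.

    ``fingerprints`` is indexed by drug id; its first ``n_continuous`` columns
    are continuous descriptors and the remaining columns are binary bits.
    """

    fingerprints: pd.DataFrame
    smiles: pd.Series | None = None
    n_continuous: int = N_CONTINUOUS

    def __post_init__(self) -> None:
        fp = self.fingerprints
        _check_unique(fp.index, "drug ids")
        vals = fp.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError("fingerprints contain non-finite values")
        bits = vals[:, self.n_continuous:]
        if not np.isin(bits, (0.0, 1.0)).all():
            raise ValidationError(
                "fingerprint bit section contains values outside {0, 1}"
            )
        if self.smiles is not None:
            self.smiles = self.smiles.reindex(fp.index)
        self.fingerprints = fp.astype(float)

    @property
    def drug_ids(self) -> pd.Index:
        return self.fingerprints.index

    @property
    def n_drugs(self) -> int:
        return self.fingerprints.shape[0]

    @property
    def fingerprint_length(self) -> int:
        return self.fingerprints.shape[1]


@dataclass
class SensitivityTable:
    """Long-form drug x cell line log10(IC50 / M) records.

    ``records`` columns: drug_id, cell_line_id, log10_ic50, observed.
    Unobserved records carry NaN in log10_ic50 and observed == False.
    """

    records: pd.DataFrame

    COLUMNS = ("drug_id", "cell_line_id", "log10_ic50", "observed")

    def __post_init__(self) -> None:
        r = self.records
        missing_cols = set(self.COLUMNS) - set(r.columns)
        if missing_cols:
            raise ValidationError(f"sensitivity table missing columns {sorted(missing_cols)}")
        r = r.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        dup = r.duplicated(subset=["drug_id", "cell_line_id"])
        if dup.any():
            pair = r.loc[dup.idxmax(), ["drug_id", "cell_line_id"]].tolist()
            raise ValidationError(f"duplicate (drug, cell line) pair: {tuple(pair)}")
        obs = r["observed"].astype(bool)
        vals = r["log10_ic50"].to_numpy(dtype=float)
        if not np.isfinite(vals[obs.to_numpy()]).all():
            raise ValidationError("observed log10_ic50 values must be finite")
        r = r.assign(observed=obs, log10_ic50=vals)
        r.loc[~obs, "log10_ic50"] = np.nan
        self.records = r

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_observed(self) -> int:
        return int(self.records["observed"].sum())

    def observed(self) -> pd.DataFrame:
        return self.records.loc[self.records["observed"]].reset_index(drop=True)


@dataclass
class FeatureMatrix:
    """Per-(drug, cell line) feature rows with labels and/or targets.

    ``features`` columns are ordered gene ids first, then chemical descriptor
    ids; ``ids`` aligns row-wise and carries drug_id / cell_line_id.
    ``label`` (0/1, 1 = active) is present in classify mode, ``target``
    (log10 IC50, molar) in regress mode; a matrix may carry both.
    """

    ids: pd.DataFrame
    features: pd.DataFrame
    gene_cols: list[str]
    chem_cols: list[str]
    label: pd.Series | None = None
    target: pd.Series | None = None
    mode: str = "classify"

    def __post_init__(self) -> None:
        if self.mode not in ("classify", "regress"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if list(self.features.columns) != list(self.gene_cols) + list(self.chem_cols):
            raise ValidationError("feature columns must be gene columns then chemistry columns")
        n = len(self.features)
        if len(self.ids) != n:
            raise ValidationError("ids and features row counts differ")
        if self.mode == "classify" and self.label is None:
            raise ValidationError("classify-mode matrix requires labels")
        if self.mode == "regress" and self.target is None:
            raise ValidationError("regress-mode matrix requires targets")
        for s, name in ((self.label, "label"), (self.target, "target")):
            if s is not None and len(s) != n:
                raise ValidationError(f"{name} length differs from feature rows")
        if self.label is not None:
            lab = self.label.to_numpy()
            if not np.isin(lab, (0, 1)).all():
                raise ValidationError("labels must be 0/1")

    @property
    def n_rows(self) -> int:
        return len(self.features)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=np.float32)

    def y(self) -> np.ndarray:
        if self.mode == "classify":
            return self.label.to_numpy(dtype=int)
        return self.target.to_numpy(dtype=float)

    def take(self, idx) -> "FeatureMatrix":
        """Row subset by positional indices, preserving mode and columns."""
        idx = np.asarray(idx)
        return FeatureMatrix(
            ids=self.ids.iloc[idx].reset_index(drop=True),
            features=self.features.iloc[idx].reset_index(drop=True),
            gene_cols=list(self.gene_cols),
            chem_cols=list(self.chem_cols),
            label=None if self.label is None else self.label.iloc[idx].reset_index(drop=True),
            target=None if self.target is None else self.target.iloc[idx].reset_index(drop=True),
            mode=self.mode,
        )

    def to_frame(self) -> pd.DataFrame:
        """Serialized layout: ids, then label/target as first data column, then features."""
        parts = [self.ids.reset_index(drop=True)]
        if self.label is not None:
            parts.append(self.label.rename("label").reset_index(drop=True))
        if self.target is not None:
            parts.append(self.target.rename("target").reset_index(drop=True))
        parts.append(self.features.reset_index(drop=True))
        return pd.concat(parts, axis=1)
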