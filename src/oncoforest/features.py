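"""Feature construction: entropy-ranked gene selection, chemical
fingerprints, and per-pair matrix assembly.

Each training row describes one (drug, cell line) pair: the cell line's
binary oncogene mutation vector (restricted to a selected gene subset)
concatenated with the drug's 1216-element chemical fingerprint — 192
continuous 2-D physicochemical/topological descriptors followed by 1024
circular-fingerprint bits of radius 3 (ECFP6-equivalent) folded to 1024.
Activity labels are a pure threshold on IC50 (active iff IC50 <= cutoff,
inclusive); regression targets are log10(IC50 / M).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .datatypes import (
    N_BITS,
    N_CONTINUOUS,
    DrugLibrary,
    FeatureMatrix,
    OncogenePanel,
    SensitivityTable,
)
from .exceptions import ChemistryError, ReferentialIntegrityError, ValidationError

#: Circular-fingerprint radius; diameter 6 bonds, i.e. ECFP6-equivalent.
FP_RADIUS = 3


@dataclass(frozen=True)
class LabelingConfig:
    """Activity labeling: a pair is *active* iff IC50 <= cutoff (molar)."""

    cutoff_molar: float = 1e-6

    def __post_init__(self) -> None:
        if not self.cutoff_molar > 0:
            raise ValidationError("activity cutoff must be strictly positive")

    @property
    def log10_cutoff(self) -> float:
        return float(np.log10(self.cutoff_molar))


def mutation_entropy(panel: OncogenePanel) -> pd.Series:
    """Binary information entropy (bits) of each gene's mutation frequency.

    H(p) = -p log2 p - (1-p) log2 (1-p) with H(0) = H(1) = 0, where p is the
    mutated fraction across cell lines. Maximal (1 bit) when half the lines
    are mutated.
    """
    if panel.n_cells == 0 or panel.n_genes == 0:
        raise ValidationError("cannot compute entropy of an empty panel")
    p = panel.mutated_fraction().to_numpy(dtype=float)
    h = np.zeros_like(p)
    for q in (p, 1.0 - p):
        nz = q > 0
        h[nz] -= q[nz] * np.log2(q[nz])
    return pd.Series(h, index=panel.gene_ids, name="entropy_bits")


def select_top_entropy_genes(panel: OncogenePanel, k: int) -> list[str]:
    """The k genes with the highest mutation entropy, descending.

    Ties are broken lexicographically by gene id.
    """
    if not 1 <= k <= panel.n_genes:
        raise ValidationError(f"k={k} out of range 1..{panel.n_genes}")
    ent = mutation_entropy(panel)
    order = sorted(ent.index, key=lambda g: (-ent[g], str(g)))
    return [str(g) for g in order[:k]]


def descriptor_names() -> list[str]:
    """The frozen manifest of 192 continuous 2-D descriptor names."""
    text = resources.files("oncoforest.data").joinpath("descriptors_192.txt").read_text()
    names = [l.strip() for l in text.splitlines() if l.strip() and not l.startswith("#")]
    if len(names) != N_CONTINUOUS:
        raise ValidationError(f"descriptor manifest has {len(names)} names, expected {N_CONTINUOUS}")
    return names


def fingerprint_column_names() -> list[str]:
    return [f"desc_{i + 1:04d}" for i in range(N_CONTINUOUS)] + [
        f"bit_{i + 1:04d}" for i in range(N_BITS)
    ]


def compute_fingerprint(smiles: str) -> np.ndarray:
    """1216-element fingerprint of a molecule given as SMILES.

    First 192 entries: continuous descriptors per the manifest; last 1024:
    radius-3 circular fingerprint folded to 1024 bits. Deterministic for a
    given SMILES within a pinned RDKit version.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import Descriptors, rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.*")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemistryError(f"unparseable SMILES: {smiles!r}")
    cont = np.array([getattr(Descriptors, n)(mol) for n in descriptor_names()], dtype=float)
    if not np.isfinite(cont).all():
        bad = [n for n, v in zip(descriptor_names(), cont) if not np.isfinite(v)]
        raise ChemistryError(f"non-finite descriptors {bad} for SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=N_BITS)
    bits = np.zeros(N_BITS, dtype=float)
    for b in gen.GetFingerprint(mol).GetOnBits():
        bits[b] = 1.0
    return np.concatenate([cont, bits])


def fingerprint_library(smiles: pd.Series) -> DrugLibrary:
    """Fingerprint every drug in a drug_id -> SMILES mapping."""
    rows = [compute_fingerprint(s) for s in smiles]
    fp = pd.DataFrame(rows, index=smiles.index, columns=fingerprint_column_names())
    return DrugLibrary(fingerprints=fp, smiles=smiles.astype(str))


def assemble_matrix(
    panel: OncogenePanel,
    drugs: DrugLibrary,
    sens: SensitivityTable,
    gene_subset: list[str] | None = None,
    labeling: LabelingConfig | None = None,
    mode: str = "classify",
) -> FeatureMatrix:
    """Join mutation vectors with drug fingerprints into per-pair rows.

    One row per observed (drug, cell line) record, in record order; feature
    columns are ``gene_subset`` order first, then fingerprint order.
    """
    labeling = labeling or LabelingConfig()
    if gene_subset is None:
        gene_subset = [str(g) for g in panel.gene_ids]
    unknown = set(gene_subset) - set(map(str, panel.gene_ids))
    if unknown:
        raise ValidationError(f"gene subset not in panel: {sorted(unknown)[:5]}")
    obs = sens.observed()
    bad_d = set(obs["drug_id"]) - set(drugs.drug_ids)
    if bad_d:
        raise ReferentialIntegrityError(f"sensitivity references unknown drugs: {sorted(bad_d)[:5]}")
    bad_c = set(obs["cell_line_id"]) - set(panel.cell_line_ids)
    if bad_c:
        raise ReferentialIntegrityError(
            f"sensitivity references unknown cell lines: {sorted(bad_c)[:5]}"
        )
    gene_block = panel.mutation[gene_subset].loc[obs["cell_line_id"]].to_numpy(dtype=np.float32)
    chem_block = drugs.fingerprints.loc[obs["drug_id"]].to_numpy(dtype=np.float32)
    chem_cols = [str(c) for c in drugs.fingerprints.columns]
    features = pd.DataFrame(
        np.hstack([gene_block, chem_block]), columns=list(gene_subset) + chem_cols
    )
    y = obs["log10_ic50"].reset_index(drop=True)
    label = target = None
    if mode == "classify":
        label = (y <= labeling.log10_cutoff).astype(int).rename("label")
    elif mode == "regress":
        target = y.rename("target")
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return FeatureMatrix(
        ids=obs[["drug_id", "cell_line_id"]].reset_index(drop=True),
        features=features,
        gene_cols=[str(g) for g in gene_subset],
        chem_cols=chem_cols,
        label=label,
        target=target,
        mode=mode,
    )
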