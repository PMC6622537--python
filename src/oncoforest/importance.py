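"""Gini-importance ranking of oncogene features and minimal-gene-set search.

Importance is the forest's mean decrease in Gini impurity attributed to a
feature. Gene features are ranked globally (one forest on all drug-cell
pairs) and per drug (one forest per drug's rows, with genes called
*top-ranking* for that drug when their importance exceeds the drug's mean
gene importance by more than two population standard deviations). The
minimal-set search retains the global top-N genes plus all chemical
descriptors and measures cross-validated classification performance as N
shrinks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .classification import RFConfig, kfold_cv, train_classifier
from .datatypes import DrugLibrary, FeatureMatrix, OncogenePanel, SensitivityTable
from .exceptions import ValidationError
from .features import LabelingConfig, assemble_matrix

#: Default subset-size grid: the 5..100-step-5 search grid merged with the
#: reported coarser grid walking down from 125.
DEFAULT_SUBSET_SIZES: tuple[int, ...] = tuple(sorted(
    set(range(5, 101, 5)) | {125, 110, 95, 80, 65, 50, 40, 30}
))

#: Minimum records a drug needs before a per-drug forest is attempted.
MIN_RECORDS_PER_DRUG = 10


@dataclass
class ImportanceTable:
    """Ranked feature importances; rank 1 = most important.

    Ties in importance are broken lexicographically by feature id.
    """

    entries: pd.DataFrame  # columns: feature_id, gini_importance, rank
    scope: str = "global"

    def top(self, n: int) -> list[str]:
        return self.entries.nsmallest(n, "rank")["feature_id"].tolist()


def _rank(imp: pd.Series, scope: str) -> ImportanceTable:
    df = pd.DataFrame({"feature_id": imp.index.astype(str), "gini_importance": imp.values})
    df = df.sort_values(
        ["gini_importance", "feature_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return ImportanceTable(entries=df, scope=scope)


def rank_gene_importance(matrix: FeatureMatrix, cfg: RFConfig) -> ImportanceTable:
    """Gini importance of the gene columns from one forest on all rows."""
    model = train_classifier(matrix, cfg)
    imp = model.gini_importance().loc[list(matrix.gene_cols)]
    return _rank(imp, scope="global")


def per_drug_top_genes(
    panel: OncogenePanel,
    drugs: DrugLibrary,
    sens: SensitivityTable,
    cfg: RFConfig,
    labeling: LabelingConfig | None = None,
) -> tuple[dict[str, list[str]], pd.Series]:
    """Top-ranking genes per drug by the mean + 2 SD rule.

    For each drug, a forest is trained on that drug's rows only (gene
    features only — the drug's fingerprint is constant within its rows), and
    genes whose importance exceeds mean + 2 * population SD of that drug's
    gene importances are called top-ranking. Returns the per-drug gene sets
    and, per gene, the number of drugs for which it is top-ranking.
    """
    matrix = assemble_matrix(panel, drugs, sens, None, labeling, mode="classify")
    row_drug = matrix.ids["drug_id"].to_numpy()
    top_sets: dict[str, list[str]] = {}
    counts = pd.Series(0, index=[str(g) for g in panel.gene_ids], dtype=int)
    for d in drugs.drug_ids:
        idx = np.flatnonzero(row_drug == d)
        if len(idx) < MIN_RECORDS_PER_DRUG:
            warnings.warn(f"drug {d}: fewer than {MIN_RECORDS_PER_DRUG} records; skipped")
            continue
        sub = matrix.take(idx)
        sub = FeatureMatrix(
            ids=sub.ids, features=sub.features[list(sub.gene_cols)],
            gene_cols=list(sub.gene_cols), chem_cols=[], label=sub.label,
            mode="classify",
        )
        if sub.label.nunique() < 2:
            warnings.warn(f"drug {d}: records of a single class; skipped")
            continue
        model = train_classifier(
            sub, RFConfig(cfg.n_trees, cfg.m_try, child_seed(cfg.seed, "perdrug", str(d)))
        )
        imp = model.gini_importance()
        thresh = imp.mean() + 2.0 * imp.std(ddof=0)
        top = sorted(imp.index[imp > thresh])
        top_sets[str(d)] = [str(g) for g in top]
        counts.loc[top_sets[str(d)]] += 1
    return top_sets, counts.rename("n_drugs_top_ranking")


def minimal_gene_search(
    panel: OncogenePanel,
    drugs: DrugLibrary,
    sens: SensitivityTable,
    cfg: RFConfig,
    labeling: LabelingConfig | None = None,
    subset_sizes: list[int] | None = None,
    ranking: ImportanceTable | None = None,
    k: int = 5,
) -> pd.DataFrame:
    """Cross-validated metrics as the gene set shrinks to the top-N genes.

    For each size N, the global top-N genes (by Gini importance on the full
    matrix) plus all chemical descriptors are retained and k-fold CV is run.
    N = 0 measures the chemistry-only model. Returns one row per size with
    accuracy / sensitivity / specificity / kappa means and SDs.
    """
    sizes = DEFAULT_SUBSET_SIZES if subset_sizes is None else list(subset_sizes)
    if len(sizes) == 0:
        raise ValidationError("subset_sizes must be non-empty")
    if max(sizes) > panel.n_genes:
        raise ValidationError(f"subset size {max(sizes)} exceeds gene count {panel.n_genes}")
    full = assemble_matrix(panel, drugs, sens, None, labeling, mode="classify")
    if ranking is None:
        ranking = rank_gene_importance(full, cfg)
    rows = []
    for n in sorted(set(int(s) for s in sizes), reverse=True):
        # keep panel column order so N = all genes reproduces the full matrix
        chosen = set(ranking.top(n)) if n > 0 else set()
        genes = [g for g in full.gene_cols if g in chosen]
        mat = FeatureMatrix(
            ids=full.ids,
            features=full.features[genes + list(full.chem_cols)],
            gene_cols=genes, chem_cols=list(full.chem_cols),
            label=full.label, mode="classify",
        )
        cv = kfold_cv(mat, cfg, k=k, seed=cfg.seed)
        row = {"n_genes": n}
        for metric in ("accuracy", "sensitivity", "specificity", "kappa"):
            row[metric] = cv.mean(metric)
            row[f"{metric}_sd"] = cv.sd(metric)
        rows.append(row)
    return pd.DataFrame(rows).sort_values("n_genes", ascending=False).reset_index(drop=True)
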