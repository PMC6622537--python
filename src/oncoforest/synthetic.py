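"""Ground-truth synthetic screening data.

Emulates a GDSC-like panel — several hundred cancer cell lines screened
against tens of drugs — from a fully known generative model so that every
downstream stage (gene selection, forest training, importance ranking,
imputation, blind validation) can be validated by signal recovery:

    log10 IC50(d, c) = mu + alpha(d) + beta(c)
                       + sum_k gamma_k * mut(c, g_k) * fp(d, f_k) + eps,
    eps ~ Normal(0, sigma^2),

with values clipped to the observed physical range [-10.3, -0.4] log10 M
(5e-11 M .. 0.4 M). Mutations are independent Bernoulli draws with
heterogeneous per-gene frequencies; fingerprints are independent bits with
per-bit densities plus iid standard-normal continuous descriptors. Drug
offsets alpha(d) are partly a linear function of the drug's continuous
descriptors (chemically informative, so held-out drugs remain predictable)
and partly idiosyncratic. Missingness is MCAR: a fixed fraction of records
is flagged unobserved uniformly at random.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .datatypes import (
    LOG10_IC50_MAX,
    LOG10_IC50_MIN,
    DrugLibrary,
    OncogenePanel,
    SensitivityTable,
)
from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class GroundTruthModel:
    """All planted parameters of the synthetic screen.

    Structural fields left as ``None`` are drawn once, deterministically from
    ``seed``, by :func:`generate_dataset` (the returned model carries the
    realized values, and is what the ground-truth sidecar records).
    """

    n_cells: int = 300
    n_drugs: int = 40
    n_genes: int = 145
    n_continuous: int = 192
    n_bits: int = 1024
    n_causal_genes: int = 10
    n_causal_bits: int = 10
    effect_magnitude: float = 1.0
    baseline_mu: float = -6.0
    noise_sd: float = 0.5
    cell_offset_sd: float = 0.25
    drug_offset_sd: float = 1.0
    #: fraction of drug-offset variance explained by continuous descriptors
    drug_offset_chem_fraction: float = 0.75
    missing_fraction: float = 0.0
    seed: int = 0
    # realized structural parameters (None until drawn)
    mutation_freqs: np.ndarray | None = None
    bit_densities: np.ndarray | None = None
    causal_genes: list[str] | None = None
    causal_bits: list[str] | None = None
    interaction_effects: np.ndarray | None = None  # aligned with causal pairs
    drug_offsets: np.ndarray | None = None
    cell_offsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if not 0 <= self.missing_fraction < 1:
            raise ConfigurationError("missing_fraction must be in [0, 1)")
        if self.n_causal_genes > self.n_genes:
            raise ConfigurationError("more causal genes than genes")
        if self.n_causal_bits > self.n_bits:
            raise ConfigurationError("more causal bits than fingerprint bits")
        for n in (self.n_cells, self.n_drugs, self.n_genes):
            if n < 1:
                raise ConfigurationError("n_cells, n_drugs, n_genes must be >= 1")
        if self.mutation_freqs is not None:
            f = np.asarray(self.mutation_freqs, dtype=float)
            if not ((f > 0) & (f < 1)).all():
                raise ConfigurationError("mutation_freqs must lie strictly inside (0, 1)")
            self.mutation_freqs = f

    # -- id helpers -------------------------------------------------------
    def gene_ids(self) -> list[str]:
        return [f"gene_{i + 1:03d}" for i in range(self.n_genes)]

    def cell_ids(self) -> list[str]:
        return [f"cell_{i + 1:04d}" for i in range(self.n_cells)]

    def drug_ids(self) -> list[str]:
        return [f"drug_{i + 1:03d}" for i in range(self.n_drugs)]

    def bit_ids(self) -> list[str]:
        return [f"bit_{i + 1:04d}" for i in range(self.n_bits)]

    def desc_ids(self) -> list[str]:
        return [f"desc_{i + 1:04d}" for i in range(self.n_continuous)]

    # -- structural draws -------------------------------------------------
    def realized(self) -> "GroundTruthModel":
        """A copy with all structural parameters drawn (from ``seed``)."""
        m = dataclasses.replace(self)
        rng = np.random.default_rng([int(self.seed) % (2**31), 0xC0FFEE])
        if m.mutation_freqs is None:
            m.mutation_freqs = rng.uniform(0.05, 0.5, size=m.n_genes)
        if m.causal_genes is None:
            idx = rng.choice(m.n_genes, size=m.n_causal_genes, replace=False)
            m.causal_genes = [m.gene_ids()[i] for i in sorted(idx)]
            # causal oncogenes are the frequently mutated ones (TP53-like):
            # give them mutation frequencies in the informative range
            m.mutation_freqs = np.array(m.mutation_freqs, dtype=float)
            m.mutation_freqs[sorted(idx)] = rng.uniform(0.20, 0.50, size=m.n_causal_genes)
        if m.bit_densities is None:
            m.bit_densities = rng.uniform(0.02, 0.30, size=m.n_bits)
        if m.causal_bits is None:
            bidx = rng.choice(m.n_bits, size=m.n_causal_bits, replace=False)
            m.causal_bits = [m.bit_ids()[i] for i in sorted(bidx)]
            # pharmacophore-like substructures are common scaffolds
            m.bit_densities = np.array(m.bit_densities, dtype=float)
            m.bit_densities[sorted(bidx)] = rng.uniform(0.30, 0.60, size=m.n_causal_bits)
        if m.interaction_effects is None:
            # one causal bit per causal gene (cycled), signed effect
            k = m.n_causal_genes
            signs = rng.choice([-1.0, 1.0], size=k)
            m.interaction_effects = signs * m.effect_magnitude
        m.interaction_effects = np.asarray(m.interaction_effects, dtype=float)
        return m

    def causal_pairs(self) -> list[tuple[str, str, float]]:
        """(gene, bit, coefficient) triples of the planted interactions."""
        m = self if self.causal_genes is not None else self.realized()
        pairs = []
        for k, g in enumerate(m.causal_genes):
            b = m.causal_bits[k % len(m.causal_bits)]
            pairs.append((g, b, float(m.interaction_effects[k])))
        return pairs

    # -- closed-form moments ----------------------------------------------
    def analytic_log_ic50_variance(self) -> float:
        """Pre-clipping variance of log10 IC50 implied by the coefficients.

        Interaction terms are independent Bernoulli products (distinct genes,
        bits cycled but genes independent), so
        Var = sd_alpha^2 + sd_beta^2 + sum_k gamma_k^2 pq(1 - pq) + sigma^2
        plus covariance between terms sharing a causal bit.
        """
        m = self if self.causal_genes is not None else self.realized()
        gid = {g: i for i, g in enumerate(m.gene_ids())}
        bid = {b: i for i, b in enumerate(m.bit_ids())}
        pairs = m.causal_pairs()
        var = m.drug_offset_sd**2 + m.cell_offset_sd**2 + m.noise_sd**2
        for g, b, gamma in pairs:
            p = m.mutation_freqs[gid[g]]
            q = m.bit_densities[bid[b]]
            var += gamma**2 * p * q * (1 - p * q)
        # covariance of pairs (k, l) sharing the same bit: g_k, g_l distinct
        for i in range(len(pairs)):
            for j in range(i + 1, len(pairs)):
                gi, bi, ci = pairs[i]
                gj, bj, cj = pairs[j]
                if bi == bj:
                    p1, p2 = m.mutation_freqs[gid[gi]], m.mutation_freqs[gid[gj]]
                    q = m.bit_densities[bid[bi]]
                    var += 2 * ci * cj * p1 * p2 * q * (1 - q)
        return float(var)

    def _structural_samples(self, n: int = 200_000) -> np.ndarray:
        """Monte-Carlo draws of the structural sum (everything but mu and eps)."""
        m = self if self.causal_genes is not None else self.realized()
        rng = np.random.default_rng([int(self.seed) % (2**31), 0xBA1A9CE])
        gid = {g: i for i, g in enumerate(m.gene_ids())}
        bid = {b: i for i, b in enumerate(m.bit_ids())}
        s = rng.normal(0.0, m.drug_offset_sd, n) + rng.normal(0.0, m.cell_offset_sd, n)
        bit_draws: dict[str, np.ndarray] = {}
        for g, b, gamma in m.causal_pairs():
            if b not in bit_draws:
                bit_draws[b] = (rng.random(n) < m.bit_densities[bid[b]]).astype(float)
            mut = (rng.random(n) < m.mutation_freqs[gid[g]]).astype(float)
            s += gamma * mut * bit_draws[b]
        return s


def generate_dataset(
    model: GroundTruthModel,
) -> tuple[OncogenePanel, DrugLibrary, SensitivityTable, GroundTruthModel]:
    """Draw a complete synthetic screen; identical seed, identical output."""
    m = model.realized()
    rng = np.random.default_rng([int(m.seed) % (2**31), 1])

    genes, cells, drug_ids = m.gene_ids(), m.cell_ids(), m.drug_ids()
    mut = (rng.random((m.n_cells, m.n_genes)) < m.mutation_freqs).astype(float)
    panel = OncogenePanel(pd.DataFrame(mut, index=cells, columns=genes))

    cont = rng.normal(0.0, 1.0, size=(m.n_drugs, m.n_continuous))
    bits = (rng.random((m.n_drugs, m.n_bits)) < m.bit_densities).astype(float)
    fp = pd.DataFrame(
        np.hstack([cont, bits]), index=drug_ids, columns=m.desc_ids() + m.bit_ids()
    )
    drugs = DrugLibrary(fingerprints=fp, n_continuous=m.n_continuous)

    # drug offsets: chemical projection + idiosyncratic remainder
    n_w = min(5, m.n_continuous)
    w_idx = rng.choice(m.n_continuous, size=n_w, replace=False)
    w = rng.normal(0.0, 1.0, size=n_w)
    proj = cont[:, w_idx] @ w
    psd = proj.std()
    proj = proj / psd if psd > 0 else proj * 0.0
    chem_sd = m.drug_offset_sd * np.sqrt(m.drug_offset_chem_fraction)
    idio_sd = m.drug_offset_sd * np.sqrt(1.0 - m.drug_offset_chem_fraction)
    alpha = chem_sd * proj + rng.normal(0.0, idio_sd, size=m.n_drugs)
    beta = rng.normal(0.0, m.cell_offset_sd, size=m.n_cells)
    m.drug_offsets, m.cell_offsets = alpha, beta

    gid = {g: i for i, g in enumerate(genes)}
    bid = {b: i for i, b in enumerate(m.bit_ids())}
    # interaction matrix over (cell, drug)
    inter = np.zeros((m.n_cells, m.n_drugs))
    for g, b, gamma in m.causal_pairs():
        inter += gamma * np.outer(mut[:, gid[g]], bits[:, bid[b]])

    eps = rng.normal(0.0, m.noise_sd, size=(m.n_cells, m.n_drugs))
    y = m.baseline_mu + alpha[None, :] + beta[:, None] + inter + eps
    n_clip = int(((y < LOG10_IC50_MIN) | (y > LOG10_IC50_MAX)).sum())
    if n_clip:
        logger.info("clipped %d of %d synthetic log10 IC50 values to [%g, %g]",
                    n_clip, y.size, LOG10_IC50_MIN, LOG10_IC50_MAX)
    y = np.clip(y, LOG10_IC50_MIN, LOG10_IC50_MAX)

    dd, cc = np.meshgrid(np.arange(m.n_drugs), np.arange(m.n_cells))
    rec = pd.DataFrame(
        {
            "drug_id": np.array(drug_ids)[dd.ravel()],
            "cell_line_id": np.array(cells)[cc.ravel()],
            "log10_ic50": y.ravel(),
            "observed": True,
        }
    )
    n_missing = int(round(m.missing_fraction * len(rec)))
    if n_missing:
        miss = rng.choice(len(rec), size=n_missing, replace=False)
        rec.loc[miss, "observed"] = False
        rec.loc[miss, "log10_ic50"] = np.nan
    return panel, drugs, SensitivityTable(rec), m


def plant_class_balance(
    model: GroundTruthModel, cutoff_molar: float, target_active_fraction: float
) -> GroundTruthModel:
    """Shift the baseline so the expected active fraction matches a target.

    Solves E[Phi((log10 cutoff - mu - S) / sigma)] = target for mu, where S
    is the structural sum sampled from the generative distribution. Raises
    when no baseline inside the physical IC50 range reaches the target.
    """
    if not 0 < target_active_fraction < 1:
        raise ConfigurationError("target_active_fraction must be in (0, 1)")
    c = float(np.log10(cutoff_molar))
    if not LOG10_IC50_MIN < c < LOG10_IC50_MAX:
        raise ConfigurationError(
            f"cutoff log10 {c:.2f} outside the clipped IC50 range "
            f"[{LOG10_IC50_MIN}, {LOG10_IC50_MAX}]"
        )
    m = model.realized()
    s = m._structural_samples()

    def active_fraction(mu: float) -> float:
        return float(norm.cdf((c - mu - s) / m.noise_sd).mean())

    lo, hi = LOG10_IC50_MIN, LOG10_IC50_MAX
    f_lo, f_hi = active_fraction(lo), active_fraction(hi)
    # active_fraction is decreasing in mu
    if not (f_hi <= target_active_fraction <= f_lo):
        raise ConfigurationError(
            f"target active fraction {target_active_fraction} unreachable with a "
            f"baseline inside [{lo}, {hi}] (attainable range "
            f"[{f_hi:.4f}, {f_lo:.4f}] given the clipping bounds)"
        )
    mu = brentq(lambda v: active_fraction(v) - target_active_fraction, lo, hi, xtol=1e-6)
    return dataclasses.replace(m, baseline_mu=float(mu))


def desk_preset(seed: int = 0, **overrides) -> GroundTruthModel:
    """The desk-scale study preset: 300 cell lines x 40 drugs x 145 genes,
    10 causal genes, effect magnitude 1.0, noise sd 0.5, 12,000 records."""
    return GroundTruthModel(seed=seed, **overrides)


def smoke_preset(seed: int = 0, **overrides) -> GroundTruthModel:
    """A tiny preset for fast unit tests (60 cells x 10 drugs)."""
    kw = dict(n_cells=60, n_drugs=10, n_genes=25, n_causal_genes=4, n_causal_bits=4)
    kw.update(overrides)
    return GroundTruthModel(seed=seed, **kw)


PRESETS = {"desk": desk_preset, "smoke": smoke_preset}


def write_ground_truth(model: GroundTruthModel, path) -> None:
    """Record all planted parameters as a JSON sidecar for recovery tests."""
    d = dataclasses.asdict(model)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1)


def read_ground_truth(path) -> GroundTruthModel:
    with open(path) as fh:
        d = json.load(fh)
    for k in ("mutation_freqs", "bit_densities", "interaction_effects",
              "drug_offsets", "cell_offsets"):
        if d.get(k) is not None:
            d[k] = np.asarray(d[k], dtype=float)
    return GroundTruthModel(**d)
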