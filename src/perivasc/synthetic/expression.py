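"""Synthetic expression cohorts with a planted immune/endothelial block.

Emulates a breast-cancer RNA-seq cohort of four PAM50 subtype groups with
per-sample TIL (tumour-infiltrating lymphocyte) fractions and a
co-regulated signature-gene block (containing CD3D, ICAM1, VCAM1, CD274)
elevated in high-TIL samples.  Counts are negative-binomial with a common
dispersion; Basal samples draw stochastically higher TIL fractions than
the luminal subtypes, so the planted TIL/subtype/signature association is
recoverable by the clustering arm.

Default cohort sizes are 147 Basal / 415 LumA / 176 LumB / 70 HER2
(N = 808).  The default transcriptome is a 300-gene desk-scale stand-in:
a 72-gene signature plus filler genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..transcriptomics import ExpressionMatrix

__all__ = [
    "ExprSimConfig",
    "simulate_expression",
    "simulate_de_counts",
    "default_signature_genes",
]

REQUIRED_SIGNATURE = ("CD3D", "ICAM1", "VCAM1", "CD274")

DEFAULT_N_BY_SUBTYPE = {"Basal": 147, "LumA": 415, "LumB": 176, "HER2": 70}

# Beta(a, b) TIL-fraction parameters per subtype: Basal centred near the
# 65% median of basal tumours, luminal subtypes low, HER2 intermediate.
DEFAULT_TIL_BETA = {
    "Basal": (5.2, 2.8),
    "LumA": (2.0, 8.0),
    "LumB": (2.5, 7.5),
    "HER2": (3.0, 5.0),
}


def default_signature_genes(n: int = 72) -> list[str]:
    """The default co-regulated block: the four named markers plus
    immune/endothelial filler ids, ``n`` genes in total."""
    if n < len(REQUIRED_SIGNATURE):
        raise ValueError("signature must include the four required genes")
    extras = [f"IMM{i:03d}" for i in range(1, n - len(REQUIRED_SIGNATURE) + 1)]
    return list(REQUIRED_SIGNATURE) + extras


@dataclass
class ExprSimConfig:
    """Parameters of the synthetic cohort.

    block_effect is the log2-fold elevation of signature genes in high-TIL
    samples (TIL fraction >= til_high_threshold).  nb_dispersion is the NB
    dispersion alpha in var = mu + alpha*mu^2.  library_size_range is the
    uniform range of per-sample total-count scale.
    """

    n_by_subtype: dict = field(default_factory=lambda: dict(DEFAULT_N_BY_SUBTYPE))
    n_genes: int = 300
    signature_genes: list = field(default_factory=default_signature_genes)
    block_effect: float = 1.5
    til_distribution_by_subtype: dict = field(
        default_factory=lambda: dict(DEFAULT_TIL_BETA)
    )
    til_high_threshold: float = 0.5
    nb_dispersion: float = 0.15
    library_size_range: tuple = (6.0e5, 1.2e6)
    abundance_log_sd: float = 1.2
    dl_til_noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if any(n < 0 for n in self.n_by_subtype.values()):
            raise ValueError("subtype sizes must be non-negative")
        if sum(self.n_by_subtype.values()) < 2:
            raise ValueError("need at least 2 samples")
        missing = set(REQUIRED_SIGNATURE) - set(self.signature_genes)
        if missing:
            raise ValueError(f"signature_genes must include {sorted(missing)}")
        if len(set(self.signature_genes)) != len(self.signature_genes):
            raise ValueError("duplicate signature gene ids")
        if self.n_genes < len(self.signature_genes):
            raise ValueError("n_genes must be >= number of signature genes")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be a positive interval")
        if not 0.0 < self.til_high_threshold < 1.0:
            raise ValueError("til_high_threshold must be in (0, 1)")
        for st in self.n_by_subtype:
            if st not in self.til_distribution_by_subtype:
                raise ValueError(f"no TIL distribution for subtype {st!r}")


def simulate_expression(config: ExprSimConfig) -> ExpressionMatrix:
    """Draw one synthetic cohort, deterministically per seed.

    Counts ~ NB(mean = library_size * relative abundance * 2**block_effect
    for signature genes in high-TIL samples, dispersion = nb_dispersion).
    Annotations carry subtype, TIL% ("pathologist"), a noisy DL-TIL%, and
    the planted high-TIL flag.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = list(config.signature_genes) + [
        f"GENE{i:04d}" for i in range(1, config.n_genes - len(config.signature_genes) + 1)
    ]
    sig_mask = np.zeros(len(genes), dtype=bool)
    sig_mask[: len(config.signature_genes)] = True

    sample_ids = []
    subtype_col = []
    til = []
    for st in sorted(config.n_by_subtype):
        a, b = config.til_distribution_by_subtype[st]
        n = config.n_by_subtype[st]
        til.append(rng.beta(a, b, size=n))
        subtype_col += [st] * n
        sample_ids += [f"{st}_{i + 1:03d}" for i in range(n)]
    til = np.concatenate(til) if til else np.array([])
    n_samples = len(sample_ids)
    high = til >= config.til_high_threshold

    rel = rng.lognormal(mean=0.0, sigma=config.abundance_log_sd, size=len(genes))
    rel /= rel.sum()
    lib = rng.uniform(*config.library_size_range, size=n_samples)

    mu = rel[:, None] * lib[None, :]
    mu[np.ix_(sig_mask, high)] *= 2.0 ** config.block_effect

    # NB via gamma-Poisson mixture: shape 1/alpha, scale alpha*mu
    alpha = config.nb_dispersion
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    counts = rng.poisson(lam).astype(np.int64)

    dl_til = np.clip(til + rng.normal(0.0, config.dl_til_noise_sd, n_samples), 0.0, 1.0)
    ann = pd.DataFrame(
        {
            "subtype": subtype_col,
            "til_pct": 100.0 * til,
            "dl_til_pct": 100.0 * dl_til,
            "high_til": high,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    values = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                          columns=ann.index)
    return ExpressionMatrix(values=values, annotations=ann, scale="counts")


def simulate_de_counts(
    n_genes: int = 300,
    n_per_group: int = 20,
    n_de: int = 30,
    log2fc: float = 2.0,
    dispersion: float = 0.1,
    library_size_range: tuple = (8.0e4, 1.2e5),
    abundance_log_sd: float = 1.0,
    seed: int = 0,
):
    """Two-group NB count fixture with known differential genes.

    The first ``n_de`` genes carry a true log2 fold change of ``log2fc``
    (group B over group A); the rest are null.  Returns
    ``(counts DataFrame, group_a ids, group_b ids, de_gene ids)``.
    """
    if n_de > n_genes:
        raise ValueError("n_de cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    a_ids = [f"A{i:02d}" for i in range(1, n_per_group + 1)]
    b_ids = [f"B{i:02d}" for i in range(1, n_per_group + 1)]
    rel = rng.lognormal(0.0, abundance_log_sd, n_genes)
    rel /= rel.sum()
    lib = rng.uniform(*library_size_range, size=2 * n_per_group)
    mu = rel[:, None] * lib[None, :]
    mu[:n_de, n_per_group:] *= 2.0 ** log2fc
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
    counts = rng.poisson(lam).astype(np.int64)
    df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                      columns=a_ids + b_ids)
    return df, a_ids, b_ids, genes[:n_de]
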