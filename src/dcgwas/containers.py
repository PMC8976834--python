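"""In-memory containers shared across the pipeline.

Genotypes are held as a dense samples x variants matrix of additive
dosages (0/1/2 alternate-allele copies, -1 for missing) with optional
per-genotype quality (GQ) and allele-depth (AD) channels, alongside
pandas tables of sample and variant metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Samples x variants additive dosage matrix.

    Parameters
    ----------
    dosages
        int8 array of shape (n_samples, n_variants); entries in {0, 1, 2}
        or ``MISSING`` (-1).
    samples
        Sample identifiers, length n_samples.
    variants
        Variant metadata table indexed by variant id, with at least
        ``chrom``, ``pos``, ``ref``, ``alt`` columns.
    gq
        Optional per-genotype quality scores, same shape as ``dosages``.
    ad_ref, ad_alt
        Optional per-genotype read depths supporting the reference and
        alternate allele.
    """

    dosages: np.ndarray
    samples: pd.Index
    variants: pd.DataFrame
    gq: np.ndarray | None = None
    ad_ref: np.ndarray | None = None
    ad_alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = pd.Index(self.samples, name="sample_id")
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        for name in ("gq", "ad_ref", "ad_alt"):
            chan = getattr(self, name)
            if chan is not None and chan.shape != self.dosages.shape:
                raise ValueError(f"{name} channel shape mismatch")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> pd.Index:
        return self.variants.index

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def missingness(self) -> np.ndarray:
        """Per-variant fraction of missing genotypes."""
        return self.missing_mask().mean(axis=0)

    def alt_allele_freq(self) -> np.ndarray:
        """Per-variant alternate-allele frequency over non-missing calls."""
        d = self.dosages
        obs = d != MISSING
        n_called = obs.sum(axis=0)
        alt = np.where(obs, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)

    def minor_allele_freq(self) -> np.ndarray:
        af = self.alt_allele_freq()
        return np.minimum(af, 1.0 - af)

    def genotype_counts(self) -> np.ndarray:
        """Per-variant (hom-ref, het, hom-alt) counts, shape (n_variants, 3)."""
        d = self.dosages
        return np.stack([(d == g).sum(axis=0) for g in (0, 1, 2)], axis=1)

    def subset(
        self,
        sample_ids: pd.Index | np.ndarray | list | None = None,
        variant_ids: pd.Index | np.ndarray | list | None = None,
    ) -> "GenotypeMatrix":
        """Return a copy restricted to the given samples and/or variants."""
        srows = (
            slice(None)
            if sample_ids is None
            else self.samples.get_indexer(pd.Index(sample_ids))
        )
        vcols = (
            slice(None)
            if variant_ids is None
            else self.variants.index.get_indexer(pd.Index(variant_ids))
        )
        if not isinstance(srows, slice) and (np.asarray(srows) < 0).any():
            raise KeyError("unknown sample id in subset")
        if not isinstance(vcols, slice) and (np.asarray(vcols) < 0).any():
            raise KeyError("unknown variant id in subset")

        def take(chan):
            if chan is None:
                return None
            return chan[srows][:, vcols].copy()

        return GenotypeMatrix(
            dosages=self.dosages[srows][:, vcols].copy(),
            samples=self.samples[srows] if not isinstance(srows, slice) else self.samples,
            variants=self.variants.iloc[vcols] if not isinstance(vcols, slice) else self.variants,
            gq=take(self.gq),
            ad_ref=take(self.ad_ref),
            ad_alt=take(self.ad_alt),
        )


@dataclass
class TruthLedger:
    """Ground truth recorded by the simulator for parameter-recovery tests.

    Attributes
    ----------
    variants
        Per-variant table: true MAF and per-phenotype log-odds effects
        (``beta_case_disease``, ``beta_ctrl_a_disease``,
        ``beta_ctrl_b_disease``) plus one ``beta_trait_<name>`` column per
        scored trait.
    genes
        Per-gene true burden log-odds per phenotype.
    samples
        Per-sample latent trait scores and simulated disease statuses.
    prevalence
        Population prevalence used for each phenotype.
    """

    variants: pd.DataFrame
    genes: pd.DataFrame
    samples: pd.DataFrame
    prevalence: dict = field(default_factory=dict)
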