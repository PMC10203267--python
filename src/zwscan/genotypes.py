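"""The samples × sites dosage container shared by all population statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # sentinel in the int8 dosage matrix

SEXES = ("F", "M", "unknown")
SUBGROUPS = ("wild", "Cultivar_I", "Cultivar_II", "Cultivar_III", "other")


@dataclass
class GenotypeMatrix:
    """Diploid allele dosages (0/1/2, -1 = missing) with per-sample labels.

    ``dosage`` has shape (n_samples, n_sites); sites are ordered by
    (chrom, pos). Sex labels are 'F'/'M'/'unknown'; subgroup labels are
    free strings ('wild', 'Cultivar_I', ...).
    """

    samples: list[str]
    sex: np.ndarray          # str per sample
    subgroup: np.ndarray     # str per sample
    chrom: np.ndarray        # str per site
    pos: np.ndarray          # int per site, 1-based
    ref: np.ndarray
    alt: np.ndarray
    dp: np.ndarray           # site depth
    qual: np.ndarray         # site quality
    dosage: np.ndarray       # int8 (n_samples, n_sites)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n_samples, n_sites = self.dosage.shape
        if len(self.samples) != n_samples:
            raise ValueError("dosage rows != number of samples")
        for name, arr, n in (
            ("sex", self.sex, n_samples),
            ("subgroup", self.subgroup, n_samples),
            ("chrom", self.chrom, n_sites),
            ("pos", self.pos, n_sites),
            ("ref", self.ref, n_sites),
            ("alt", self.alt, n_sites),
            ("dp", self.dp, n_sites),
            ("qual", self.qual, n_sites),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        bad = set(np.unique(self.sex)) - set(SEXES)
        if bad:
            raise ValueError(f"unknown sex labels: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[1]

    def sample_mask(self, *, sex: str | None = None, subgroup: str | None = None) -> np.ndarray:
        mask = np.ones(self.n_samples, dtype=bool)
        if sex is not None:
            mask &= np.asarray(self.sex) == sex
        if subgroup is not None:
            mask &= np.asarray(self.subgroup) == subgroup
        return mask

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=self.samples,
            sex=self.sex,
            subgroup=self.subgroup,
            chrom=np.asarray(self.chrom)[idx],
            pos=np.asarray(self.pos)[idx],
            ref=np.asarray(self.ref)[idx],
            alt=np.asarray(self.alt)[idx],
            dp=np.asarray(self.dp)[idx],
            qual=np.asarray(self.qual)[idx],
            dosage=self.dosage[:, idx],
            meta=dict(self.meta),
        )

    def take_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            samples=[s for s, keep in zip(self.samples, mask) if keep],
            sex=np.asarray(self.sex)[mask],
            subgroup=np.asarray(self.subgroup)[mask],
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            dp=self.dp,
            qual=self.qual,
            dosage=self.dosage[mask, :],
            meta=dict(self.meta),
        )

    def allele_counts(self, sample_mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, called allele count) over non-missing genotypes."""
        d = self.dosage if sample_mask is None else self.dosage[sample_mask, :]
        called = d != MISSING
        ac = np.where(called, d, 0).sum(axis=0).astype(np.int64)
        an = 2 * called.sum(axis=0).astype(np.int64)
        return ac, an

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.samples, "sex": self.sex, "subgroup": self.subgroup}
        )
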