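"""Linkage-disequilibrium estimation from a reference genotype panel.

LD is computed as the Pearson correlation of unphased dosages (entries in
[0, 2]), the standard reference-panel practice; haplotype-level D' is out of
scope.  Missing dosages are handled pairwise-complete, but any variant with
more than 10% missingness is rejected outright.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class LDError(ValueError):
    pass


@dataclass
class GenotypePanel:
    """Reference genotypes: ``dosages`` is samples × variants, NaN = missing."""

    sample_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray
    variants: pd.DataFrame | None = None  # optional ID/CHR/POS/EA/NEA catalogue

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise LDError("dosage matrix shape does not match sample/variant ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def allele_freq(self) -> np.ndarray:
        """Effect-allele (counted-allele) frequency per variant."""
        return np.nanmean(self.dosages, axis=0) / 2.0


@dataclass
class LDMatrix:
    """Symmetric matrix of dosage correlations r, indexed by variant id."""

    ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (len(self.ids), len(self.ids)):
            raise LDError("LD matrix shape does not match ids")
        self._index = {v: i for i, v in enumerate(self.ids)}

    def __contains__(self, vid: str) -> bool:
        return vid in self._index

    def loc(self, vid: str) -> int:
        try:
            return self._index[vid]
        except KeyError:
            raise LDError(f"variant {vid!r} not in LD matrix") from None

    def submatrix(self, ids: Sequence[str]) -> "LDMatrix":
        idx = np.array([self.loc(v) for v in ids])
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)])


def read_panel_tsv(path) -> GenotypePanel:
    """Read a plain dosage matrix: first column sample id, variants as columns."""
    df = pd.read_csv(path, sep="\t")
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    dos = df.iloc[:, 1:]
    return GenotypePanel(sample_ids, [str(c) for c in dos.columns], dos.to_numpy(float))


def read_panel_vcf(path) -> GenotypePanel:
    """Build a dosage panel from a VCF's GT fields (biallelic records only)."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    ids, rows, meta = [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        gts = np.array([g[0] + g[1] if g[0] >= 0 and g[1] >= 0 else np.nan
                        for g in rec.genotypes], dtype=float)
        ids.append(vid)
        rows.append(gts)
        meta.append((vid, rec.CHROM, rec.POS, rec.ALT[0], rec.REF))
    variants = pd.DataFrame(meta, columns=["ID", "CHR", "POS", "EA", "NEA"])
    return GenotypePanel(sample_ids, ids, np.array(rows).T, variants)


def compute_ld(panel: GenotypePanel, variant_ids: Sequence[str] | None = None) -> LDMatrix:
    """Pairwise-complete Pearson correlation of dosages.

    Zero-variance variants are excluded with a warning; variants with more
    than 10% missing dosages are a hard error.
    """
    if variant_ids is None:
        variant_ids = panel.variant_ids
    pos = {v: i for i, v in enumerate(panel.variant_ids)}
    missing = [v for v in variant_ids if v not in pos]
    if missing:
        raise LDError(f"variants not in panel: {missing[:5]}")
    cols = [pos[v] for v in variant_ids]
    X = panel.dosages[:, cols]

    miss_frac = np.mean(np.isnan(X), axis=0)
    too_missing = np.asarray(variant_ids)[miss_frac > 0.10]
    if too_missing.size:
        raise LDError(f"variants with >10% missing dosages: {list(too_missing[:5])}")
    nonmiss = np.sum(~np.isnan(X), axis=0)
    if np.any(nonmiss < 2):
        raise LDError("variants with fewer than 2 non-missing dosages")

    variances = np.nanvar(X, axis=0)
    keep = variances > 0
    if not keep.all():
        dropped = list(np.asarray(variant_ids)[~keep])
        log.warning("compute_ld: excluding %d zero-variance variants: %s",
                    len(dropped), dropped[:5])
    kept_ids = [v for v, k in zip(variant_ids, keep) if k]
    X = X[:, keep]
    if np.isnan(X).any():
        r = pd.DataFrame(X).corr(method="pearson").to_numpy()  # pairwise-complete
    else:
        r = np.corrcoef(X, rowvar=False)
        if r.ndim == 0:  # single variant
            r = np.array([[1.0]])
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(kept_ids, r)


def r2(ld: LDMatrix, id1: str, id2: str) -> float:
    """Squared dosage correlation between two variants."""
    return float(ld.r[ld.loc(id1), ld.loc(id2)] ** 2)


def find_proxies(ld: LDMatrix, vid: str, r2_min: float = 0.8) -> list[tuple[str, float]]:
    """Variants with r² strictly above ``r2_min``, descending, excluding the query."""
    if not 0 < r2_min <= 1:
        raise ValueError("r2_min must be in (0, 1]")
    i = ld.loc(vid)
    rsq = ld.r[i] ** 2
    hits = [(v, float(q)) for v, q in zip(ld.ids, rsq) if v != vid and q > r2_min]
    hits.sort(key=lambda t: (-t[1], t[0]))
    return hits
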