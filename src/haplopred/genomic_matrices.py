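"""Quantitative-genetics model matrices and genomic relationship matrices.

Codings follow the genetic partition of genotypic values:

* SNP additive: an individual with x copies of the counted allele (sample
  frequency p) is coded x - 2p, so columns are centered at the sample
  frequency.
* SNP dominance: genotypes with {2, 1, 0} copies are coded
  {-2q^2, 2pq, -2p^2} with q = 1 - p; the column has expectation zero and
  is orthogonal to the additive column under Hardy-Weinberg proportions.
* Haplotype additive: each block allele l with frequency p_l contributes
  one column coding c_l - 2p_l, where c_l in {0, 1, 2} is the number of
  copies the individual carries; the row-sum over a block's columns is
  identically zero.

Each cross-product W W' is scaled by its trace normalizer
k = tr(W W') / n, which forces the relationship matrix to have mean
diagonal exactly 1 and makes the matrices invariant to rescaling of W.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import GenotypePanel
from .haploblock import HaplotypeBlockSet


@dataclass
class ModelMatrices:
    """Model matrices for the components present in an analysis.

    ``w_alpha``/``w_delta`` are n x m; ``w_alpha_h`` is n x n_ah with
    columns grouped by block (``hap_block_slices`` maps block_id to its
    column slice).  ``k_*`` are the trace normalizers tr(W W')/n.
    """

    w_alpha: np.ndarray | None = None
    w_delta: np.ndarray | None = None
    w_alpha_h: np.ndarray | None = None
    k_alpha: float | None = None
    k_delta: float | None = None
    k_alpha_h: float | None = None
    hap_block_slices: dict | None = None


@dataclass
class GRMSet:
    a_g: np.ndarray | None = None
    d_g: np.ndarray | None = None
    a_gh: np.ndarray | None = None

    def as_dict(self) -> dict:
        out = {}
        if self.a_g is not None:
            out["snp_additive"] = self.a_g
        if self.d_g is not None:
            out["snp_dominance"] = self.d_g
        if self.a_gh is not None:
            out["hap_additive"] = self.a_gh
        return out


def _check_freqs(freqs: np.ndarray) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("monomorphic SNP encountered (p in {0,1}); filter first")
    return freqs


def snp_additive_coding(dosage: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Centered allele-count coding x - 2p (columns mean-zero at sample p)."""
    freqs = _check_freqs(freqs)
    return np.asarray(dosage, dtype=float) - 2.0 * freqs[None, :]


def snp_dominance_coding(dosage: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Dominance partition coding {2,1,0} copies -> {-2q^2, 2pq, -2p^2}."""
    freqs = _check_freqs(freqs)
    dosage = np.asarray(dosage)
    p = freqs[None, :]
    q = 1.0 - p
    w = np.empty(dosage.shape, dtype=float)
    w[:] = -2.0 * p**2  # dosage 0
    w = np.where(dosage == 1, 2.0 * p * q, w)
    w = np.where(dosage == 2, -2.0 * q**2, w)
    return w


def haplotype_additive_coding(
    blockset: HaplotypeBlockSet, panel: GenotypePanel
) -> tuple[np.ndarray, dict]:
    """Multi-allelic coding: one column per block allele, code c_l - 2 p_l.

    Returns ``(W, block_slices)`` where ``block_slices[block_id]`` is the
    column slice of that block.  Requires enumerated alleles.
    """
    n = panel.n_individuals
    total_cols = 0
    for block in blockset.blocks:
        if block.hap_allele_index is None:
            raise ValueError("alleles not enumerated; call enumerate_haplotypes first")
        if abs(float(np.sum(block.allele_freqs)) - 1.0) > 1e-9:
            raise ValueError(f"block {block.block_id} allele frequencies do not sum to 1")
        total_cols += block.n_alleles

    w = np.empty((n, total_cols), dtype=float)
    slices = {}
    col = 0
    for block in blockset.blocks:
        k = block.n_alleles
        idx = block.hap_allele_index.reshape(n, 2)
        copies = np.zeros((n, k), dtype=float)
        rows = np.repeat(np.arange(n), 2)
        np.add.at(copies, (rows, idx.ravel()), 1.0)
        w[:, col : col + k] = copies - 2.0 * block.allele_freqs[None, :]
        slices[block.block_id] = slice(col, col + k)
        col += k
    return w, slices


def build_model_matrices(
    panel: GenotypePanel,
    blockset: HaplotypeBlockSet | None = None,
    components: tuple = ("snp_additive", "snp_dominance", "hap_additive"),
    snp_indices: np.ndarray | None = None,
) -> ModelMatrices:
    """Build the requested model matrices from a phased panel.

    ``snp_indices`` optionally restricts the SNP components to a subset of
    panel columns (e.g. SNPs inside a functional region's blocks); the
    haplotype component always uses the given blockset.
    """
    mm = ModelMatrices()
    dosage = panel.dosages().astype(float)
    freqs = panel.alt_freqs()
    if snp_indices is not None:
        dosage = dosage[:, snp_indices]
        freqs = freqs[snp_indices]
    n = panel.n_individuals

    if "snp_additive" in components:
        mm.w_alpha = snp_additive_coding(dosage, freqs)
        mm.k_alpha = float(np.einsum("ij,ij->", mm.w_alpha, mm.w_alpha)) / n
    if "snp_dominance" in components:
        mm.w_delta = snp_dominance_coding(dosage, freqs)
        mm.k_delta = float(np.einsum("ij,ij->", mm.w_delta, mm.w_delta)) / n
    if "hap_additive" in components:
        if blockset is None:
            raise ValueError("hap_additive requested but no blockset given")
        mm.w_alpha_h, mm.hap_block_slices = haplotype_additive_coding(blockset, panel)
        mm.k_alpha_h = float(np.einsum("ij,ij->", mm.w_alpha_h, mm.w_alpha_h)) / n
    return mm


def _grm(w: np.ndarray, k: float) -> np.ndarray:
    if k <= 0:
        raise ValueError("degenerate model matrix: zero trace normalizer")
    g = (w @ w.T) / k
    return 0.5 * (g + g.T)  # enforce exact symmetry


def build_grms(mm: ModelMatrices) -> GRMSet:
    """Relationship matrices A_g, D_g, A_gh = W W' / k with k = tr(W W')/n."""
    out = GRMSet()
    if mm.w_alpha is not None:
        out.a_g = _grm(mm.w_alpha, mm.k_alpha)
    if mm.w_delta is not None:
        out.d_g = _grm(mm.w_delta, mm.k_delta)
    if mm.w_alpha_h is not None:
        out.a_gh = _grm(mm.w_alpha_h, mm.k_alpha_h)
    return out
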