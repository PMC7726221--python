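"""Synthetic phased panels, annotations and phenotypes with known architecture.

The generator stands in for an access-restricted human cohort: it produces
multi-chromosome phased SNP panels with a tunable minor-allele-frequency
spectrum and local LD, gene/ChIP-seq-like interval annotations, and
phenotypes assembled from fixed effects, SNP additive values, SNP dominance
values, within-block additive-by-additive epistasis values and residual
noise.  Every random component is recorded in a :class:`TruthRecord` so
downstream estimators can be validated against the simulated truth.

LD model
--------
Founder haplotypes follow a first-order Markov chain along each chromosome:
each SNP's allele indicator is obtained by thresholding a latent uniform
that is either copied from the previous SNP (probability ``ld_decay``) or
drawn fresh.  Marginal allele frequencies are exact, and for two adjacent
SNPs with equal frequencies the allelic correlation equals ``ld_decay``;
with unequal frequencies the binary correlation is attenuated toward the
Frechet bound.  Diploids pair independent founder haplotypes; an optional
generation of random mating introduces relatedness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypePanel

ANNOTATION_CLASSES = ("coding", "noncoding", "chipseq")


@dataclass
class SimConfig:
    """Configuration of the phased-genotype simulator.

    Parameters
    ----------
    n_individuals
        Number of diploid individuals (>= 2).
    chromosomes
        List of ``(name, length_bp)`` pairs; lengths must be positive.
    snp_density
        Expected SNPs per megabase.
    maf_spectrum
        ``("uniform", lo, hi)`` or ``("fixed", p)`` over minor allele
        frequencies in (0, 0.5].
    ld_decay
        Copy probability of the founder Markov chain, in [0, 1).
    mating_generations
        Extra generations of random mating after founding (0 = none).
    seed
        Seed for all randomness in genotype simulation.
    """

    n_individuals: int = 500
    chromosomes: list = field(default_factory=lambda: [("1", 50_000_000), ("2", 50_000_000)])
    snp_density: float = 40.0
    maf_spectrum: tuple = ("uniform", 0.05, 0.5)
    ld_decay: float = 0.7
    mating_generations: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if not self.chromosomes:
            raise ValueError("need at least one chromosome")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        if not (0.0 <= self.ld_decay < 1.0):
            raise ValueError("ld_decay must be in [0, 1)")
        if self.snp_density <= 0:
            raise ValueError("snp_density must be positive")


def _draw_mafs(rng: np.random.Generator, spectrum: tuple, size: int) -> np.ndarray:
    kind = spectrum[0]
    if kind == "uniform":
        lo, hi = spectrum[1], spectrum[2]
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("uniform MAF bounds must satisfy 0 < lo <= hi <= 0.5")
        return rng.uniform(lo, hi, size=size)
    if kind == "fixed":
        p = spectrum[1]
        if not (0 < p <= 0.5):
            raise ValueError("fixed MAF must be in (0, 0.5]")
        return np.full(size, float(p))
    raise ValueError(f"unknown maf_spectrum kind: {kind!r}")


def simulate_genotypes(config: SimConfig) -> GenotypePanel:
    """Simulate a phased diploid panel under the founder Markov-chain model.

    Returns a :class:`GenotypePanel` with 2 * ``n_individuals`` phased
    haplotypes per chromosome and strictly increasing SNP positions.
    Deterministic for a fixed config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    n_haps = 2 * config.n_individuals

    hap_chunks: list[np.ndarray] = []
    map_chunks: list[pd.DataFrame] = []
    for name, length in config.chromosomes:
        m_c = int(round(length / 1e6 * config.snp_density))
        if m_c < 1:
            raise ValueError(
                f"chromosome {name}: snp_density {config.snp_density} yields zero SNPs"
            )
        positions = np.sort(rng.choice(length, size=m_c, replace=False)) + 1
        # alt allele is the minor allele: target alt frequency = drawn MAF
        freqs = _draw_mafs(rng, config.maf_spectrum, m_c)

        u = np.empty((n_haps, m_c))
        u[:, 0] = rng.random(n_haps)
        if m_c > 1:
            fresh = rng.random((n_haps, m_c - 1))
            copy = rng.random((n_haps, m_c - 1)) < config.ld_decay
            for j in range(1, m_c):
                u[:, j] = np.where(copy[:, j - 1], u[:, j - 1], fresh[:, j - 1])
        haps = (u < freqs[None, :]).astype(np.int8)

        hap_chunks.append(haps)
        map_chunks.append(
            pd.DataFrame(
                {
                    "chrom": name,
                    "pos": positions,
                    "ref": "A",
                    "alt": "G",
                }
            )
        )

    haplotypes = np.hstack(hap_chunks)
    snp_map = pd.concat(map_chunks, ignore_index=True)

    chrom_slices = []
    start = 0
    for chunk in hap_chunks:
        chrom_slices.append(slice(start, start + chunk.shape[1]))
        start += chunk.shape[1]

    for _ in range(config.mating_generations):
        haplotypes = _random_mating(rng, haplotypes, chrom_slices)

    return GenotypePanel(haplotypes=haplotypes, snp_map=snp_map)


def _random_mating(
    rng: np.random.Generator, haplotypes: np.ndarray, chrom_slices: list[slice]
) -> np.ndarray:
    """One generation of random mating; each parent transmits one whole
    chromosome haplotype (no recombination)."""
    n = haplotypes.shape[0] // 2
    children = np.empty_like(haplotypes)
    sires = rng.integers(0, n, size=n)
    dams = rng.integers(0, n, size=n)
    # avoid selfing where possible
    clash = sires == dams
    dams[clash] = (dams[clash] + 1) % n
    for i in range(n):
        for parent_row, parent in ((2 * i, sires[i]), (2 * i + 1, dams[i])):
            for sl in chrom_slices:
                which = rng.integers(0, 2)
                children[parent_row, sl] = haplotypes[2 * parent + which, sl]
    return children


def simulate_annotations(
    chromosomes: list,
    n_intervals: int,
    size_distribution: tuple = ("uniform", 5_000, 100_000),
    class_fractions: tuple = (0.5, 0.3, 0.2),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate gene/ChIP-seq-like annotation intervals.

    Returns a BED-convention frame (0-based half-open) with columns
    ``chrom, start, end, name, cls`` where ``cls`` is one of ``coding``,
    ``noncoding``, ``chipseq``.  Intervals of the same class may overlap.
    """
    if not chromosomes:
        raise ValueError("empty chromosome list")
    if n_intervals < 0:
        raise ValueError("n_intervals must be >= 0")
    fractions = np.asarray(class_fractions, dtype=float)
    if fractions.shape != (3,) or np.any(fractions < 0) or fractions.sum() <= 0:
        raise ValueError("class_fractions must be 3 non-negative numbers")
    fractions = fractions / fractions.sum()

    rng = np.random.default_rng(seed)
    names = [c[0] for c in chromosomes]
    lengths = np.array([c[1] for c in chromosomes], dtype=float)

    rows = []
    for i in range(n_intervals):
        kind = size_distribution[0]
        if kind == "fixed":
            size = int(size_distribution[1])
        elif kind == "uniform":
            size = int(rng.integers(size_distribution[1], size_distribution[2] + 1))
        elif kind == "lognormal":
            size = int(np.clip(rng.lognormal(size_distribution[1], size_distribution[2]), 1, None))
        else:
            raise ValueError(f"unknown size_distribution kind: {kind!r}")
        fits = lengths >= size
        if not fits.any():
            raise ValueError(f"interval size {size} exceeds every chromosome length")
        probs = np.where(fits, lengths, 0.0)
        probs = probs / probs.sum()
        ci = rng.choice(len(names), p=probs)
        start = int(rng.integers(0, lengths[ci] - size + 1))
        cls = ANNOTATION_CLASSES[rng.choice(3, p=fractions)]
        rows.append((names[ci], start, start + size, f"iv{i:05d}", cls))

    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "cls"])
    if len(df):
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return df


@dataclass
class TraitArchitecture:
    """Requested variance architecture of a simulated trait.

    Fractions are of total phenotypic variance (normalized to 1); the
    residual absorbs the remainder.  ``boxcox_lambda_inverse`` applies the
    inverse Box-Cox transform with that lambda to skew the trait (lambda = 1
    leaves the trait unchanged up to an affine shift).
    """

    additive: float = 0.3
    dominance: float = 0.0
    epistasis: float = 0.0
    n_causal_snps: int | None = None
    epistasis_pairs_per_block: int = 2
    boxcox_lambda_inverse: float | None = None
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("additive", "dominance", "epistasis"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} fraction must be >= 0")
        if self.additive + self.dominance + self.epistasis > 1.0 + 1e-12:
            raise ValueError("genetic variance fractions sum to more than 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def residual(self) -> float:
        return 1.0 - self.additive - self.dominance - self.epistasis


@dataclass
class FixedEffectsSpec:
    """Sex-like factor and age-like covariate added as fixed effects."""

    intercept: float = 10.0
    sex_effect: float = 0.5
    age_effect: float = 0.02
    age_range: tuple = (30.0, 80.0)


@dataclass
class TruthRecord:
    """Everything the phenotype simulator drew, for validating estimators."""

    fractions: dict
    additive_snps: np.ndarray
    additive_effects: np.ndarray
    dominance_snps: np.ndarray
    dominance_effects: np.ndarray
    epistasis_pairs: list  # (block_id, snp_i, snp_j, effect)
    fixed_coefficients: dict
    components: dict  # name -> n-vector (additive, dominance, epistasis, residual)
    boxcox_lambda_inverse: float | None
    phenotype_unskewed: np.ndarray


def _rescale(component: np.ndarray, target_variance: float) -> np.ndarray:
    if target_variance == 0:
        return np.zeros_like(component)
    sd = component.std(ddof=1)
    if sd == 0:
        raise ValueError("component has zero variance; cannot rescale")
    return component * np.sqrt(target_variance) / sd


def _orthogonalize(component: np.ndarray, against: list) -> np.ndarray:
    """Residualize a centered component on previously built ones.

    Keeps the variance fractions genuinely disjoint: under LD the raw
    dominance and within-block product components carry additive-direction
    signal (third-moment coupling), so each component is projected onto the
    orthocomplement of the ones built before it.
    """
    component = component - component.mean()
    basis = [v for v in against if v.std() > 0]
    if basis:
        b = np.column_stack(basis)
        coef, *_ = np.linalg.lstsq(b, component, rcond=None)
        component = component - b @ coef
    return component


def simulate_phenotypes(
    panel: GenotypePanel,
    blocks,
    truth_spec: TraitArchitecture,
    fixed_effects_spec: FixedEffectsSpec | None = None,
    seed: int = 0,
):
    """Simulate phenotypes y = Xb + additive + dominance + epistasis + e.

    Additive and dominance values use the centered SNP codings of
    :mod:`haplopred.genomic_matrices`; epistasis values are sums over SNP
    pairs sampled within the same haplotype block of cis-phase products:
    for each of an individual's two haplotypes, the product of the pair's
    centered allele indicators times the interaction effect — within-
    haplotype additive-by-additive epistasis, which a haplotype additive
    model can absorb but a SNP additive model cannot.  Components
    are orthogonalized sequentially (dominance against additive, epistasis
    against both) so the requested fractions are disjoint variance
    contributions, then rescaled so each realized sample variance equals
    its requested fraction of the (unit) total phenotypic variance exactly.

    Returns ``(phenotype_table, truth_record)`` where the table has columns
    ``id, y, sex, age`` (y is NaN for simulated-missing records).
    """
    from .genomic_matrices import snp_additive_coding, snp_dominance_coding

    rng = np.random.default_rng(seed)
    n = panel.n_individuals
    m = panel.n_snps
    spec = truth_spec
    fixed = fixed_effects_spec or FixedEffectsSpec()

    dosage = panel.dosages().astype(float)
    freqs = panel.alt_freqs()
    poly = (freqs > 0) & (freqs < 1)

    n_causal = spec.n_causal_snps if spec.n_causal_snps is not None else int(poly.sum())
    poly_idx = np.flatnonzero(poly)
    if n_causal > poly_idx.size:
        raise ValueError("n_causal_snps exceeds polymorphic SNP count")

    components: dict[str, np.ndarray] = {}

    add_idx = np.sort(rng.choice(poly_idx, size=n_causal, replace=False))
    add_eff = rng.standard_normal(n_causal)
    if spec.additive > 0:
        w_a = snp_additive_coding(dosage[:, add_idx], freqs[add_idx])
        raw = w_a @ add_eff
        components["additive"] = _rescale(raw - raw.mean(), spec.additive)
    else:
        components["additive"] = np.zeros(n)

    dom_idx = np.sort(rng.choice(poly_idx, size=n_causal, replace=False))
    dom_eff = rng.standard_normal(n_causal)
    if spec.dominance > 0:
        w_d = snp_dominance_coding(dosage[:, dom_idx], freqs[dom_idx])
        raw = _orthogonalize(w_d @ dom_eff, [components["additive"]])
        components["dominance"] = _rescale(raw, spec.dominance)
    else:
        components["dominance"] = np.zeros(n)

    epi_pairs: list[tuple] = []
    if spec.epistasis > 0:
        usable = [b for b in getattr(blocks, "blocks", [])] if blocks is not None else []
        usable = [b for b in usable if len(b.snp_indices) >= 2]
        if not usable:
            raise ValueError("epistasis fraction > 0 but no blocks with >= 2 SNPs")
        epi = np.zeros(n)
        for block in usable:
            idx = np.asarray(block.snp_indices)
            idx = idx[poly[idx]]
            if idx.size < 2:
                continue
            n_pairs = min(
                spec.epistasis_pairs_per_block, idx.size * (idx.size - 1) // 2
            )
            seen = set()
            while len(seen) < n_pairs:
                i, j = rng.choice(idx.size, size=2, replace=False)
                key = (min(i, j), max(i, j))
                seen.add(key)
            for i, j in sorted(seen):
                si, sj = int(idx[i]), int(idx[j])
                eff = rng.standard_normal()
                # cis-phase product: interaction acts within each haplotype
                for h in (0, 1):
                    hap = panel.haplotypes[h::2]
                    epi += (hap[:, si] - freqs[si]) * (hap[:, sj] - freqs[sj]) * eff
                epi_pairs.append((block.block_id, si, sj, eff))
        epi = _orthogonalize(epi, [components["additive"], components["dominance"]])
        components["epistasis"] = _rescale(epi, spec.epistasis)
    else:
        components["epistasis"] = np.zeros(n)

    components["residual"] = _rescale(rng.standard_normal(n), spec.residual)

    sex = rng.integers(0, 2, size=n)
    age = rng.uniform(*fixed.age_range, size=n)
    xb = fixed.intercept + fixed.sex_effect * sex + fixed.age_effect * age

    y = xb + sum(components.values())
    y_unskewed = y.copy()

    lam = spec.boxcox_lambda_inverse
    if lam is not None:
        shifted = y - y.min()  # >= 0 so lam * shifted + 1 > 0 for lam >= 0
        if lam == 0:
            y = np.exp(shifted)
        else:
            base = lam * shifted + 1.0
            if np.any(base <= 0):
                raise ValueError("inverse Box-Cox domain violated; use lambda >= 0")
            y = base ** (1.0 / lam)

    if spec.missing_rate > 0:
        y = y.astype(float)
        y[rng.random(n) < spec.missing_rate] = np.nan

    table = pd.DataFrame({"id": panel.samples, "y": y, "sex": sex, "age": age})
    record = TruthRecord(
        fractions={
            "additive": spec.additive,
            "dominance": spec.dominance,
            "epistasis": spec.epistasis,
            "residual": spec.residual,
        },
        additive_snps=add_idx,
        additive_effects=add_eff,
        dominance_snps=dom_idx,
        dominance_effects=dom_eff,
        epistasis_pairs=epi_pairs,
        fixed_coefficients={
            "intercept": fixed.intercept,
            "sex": fixed.sex_effect,
            "age": fixed.age_effect,
        },
        components=components,
        boxcox_lambda_inverse=lam,
        phenotype_unskewed=y_unskewed,
    )
    return table, record
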