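"""Haplotype-epistasis heritability by the heritability-based method.

A haplotype additive value is hypothesized to be the sum of the block's SNP
additive values and a within-block additive-by-additive epistasis value,
minus a possible haplotype loss.  Under the invariance of GBLUP/GREML to
duplicated SNPs, the excess of a haplotype model's total heritability over
the matched SNP model's total heritability estimates the within-block
epistasis heritability:

    h_E^2 = h_g^2 - h_s^2

where h_g^2 sums the component heritabilities of the haplotype model
(Models 1-4) and h_s^2 those of the matched SNP baseline: Models 2 and 4
are differenced against the additive-only SNP model (Model 6), Models 1
and 3 against the additive + dominance SNP model (Model 5).  The relative
form h_Er^2 divides by the baseline SNP additive heritability.  Negative
estimates indicate haplotype loss (the haplotype model capturing SNP
additive signal less accurately than the SNP model) and are reported, not
clamped.  Known caveat: this differencing estimator is upward biased when
the haplotype model absorbs non-epistatic variance.
"""

from __future__ import annotations

from dataclasses import dataclass

from .validation import MODEL_COMPONENTS, HAPLOTYPE_MODELS, SNP_MODELS

#: SNP baseline model matched to each haplotype model.
BASELINE_FOR = {1: 5, 2: 6, 3: 5, 4: 6}


@dataclass
class EpistasisEstimate:
    h_e2: float
    h_er2: float | None  # fraction; None when no valid denominator
    hap_model_id: int
    snp_model_id: int
    h_g2: float
    h_s2: float
    constituents: dict
    haplotype_loss: bool

    @property
    def h_er2_pct(self) -> float | None:
        return None if self.h_er2 is None else 100.0 * self.h_er2


def total_heritability(heritabilities: dict, model_id: int) -> float:
    """Sum the component heritabilities a given model prescribes.

    ``heritabilities`` maps component names (``snp_additive``,
    ``snp_dominance``, ``hap_additive``) to estimates; a ``residual``
    entry is ignored.  The non-residual key set must match the model's
    component list exactly.
    """
    if model_id not in MODEL_COMPONENTS:
        raise ValueError(f"unknown model id {model_id}")
    required = set(MODEL_COMPONENTS[model_id])
    provided = set(heritabilities) - {"residual"}
    missing = required - provided
    if missing:
        raise ValueError(f"model {model_id} requires missing component(s): {sorted(missing)}")
    extra = provided - required
    if extra:
        raise ValueError(f"component(s) {sorted(extra)} inconsistent with model {model_id}")
    return float(sum(heritabilities[c] for c in required))


def epistasis_heritability(h_g2: float, h_s2: float, hap_model_id: int, snp_model_id: int) -> float:
    """h_E^2 = h_g^2 - h_s^2 for a correctly paired model combination.

    May be negative (haplotype loss exceeding epistasis); the sign is
    preserved.
    """
    if hap_model_id not in HAPLOTYPE_MODELS:
        raise ValueError(f"model {hap_model_id} is not a haplotype model")
    if snp_model_id not in SNP_MODELS:
        raise ValueError(f"model {snp_model_id} is not a SNP model")
    expected = BASELINE_FOR[hap_model_id]
    if snp_model_id != expected:
        raise ValueError(
            f"haplotype model {hap_model_id} must be differenced against "
            f"SNP model {expected}, not {snp_model_id}"
        )
    return float(h_g2) - float(h_s2)


def relative_epistasis_heritability(
    h_e2: float, baseline_additive_h2: float, hap_model_id: int
) -> float:
    """h_Er^2 = h_E^2 over the baseline SNP additive heritability.

    For Models 2 and 4 the denominator is the additive heritability from
    the additive-only SNP model; for Models 1 and 3 it is the additive
    heritability from the additive + dominance SNP model.  Reported as a
    fraction (multiply by 100 for percent).
    """
    if hap_model_id not in HAPLOTYPE_MODELS:
        raise ValueError(f"model {hap_model_id} is not a haplotype model")
    if baseline_additive_h2 <= 0:
        raise ZeroDivisionError("baseline SNP additive heritability must be > 0")
    return float(h_e2) / float(baseline_additive_h2)


def estimate_epistasis(hap_fit, snp_fit, hap_model_id: int) -> EpistasisEstimate:
    """Full HBM estimate from a haplotype-model fit and its SNP baseline fit.

    ``hap_fit``/``snp_fit`` are :class:`~haplopred.greml_gblup.FitResult`
    objects produced under the haplotype model and its matched SNP
    baseline (Model 6 for haplotype Models 2/4, Model 5 for Models 1/3).
    """
    snp_model_id = BASELINE_FOR[hap_model_id]
    hap_h2 = {k: v for k, v in hap_fit.heritabilities.items() if k != "residual"}
    snp_h2 = {k: v for k, v in snp_fit.heritabilities.items() if k != "residual"}
    h_g2 = total_heritability(hap_h2, hap_model_id)
    h_s2 = total_heritability(snp_h2, snp_model_id)
    h_e2 = epistasis_heritability(h_g2, h_s2, hap_model_id, snp_model_id)
    denom = snp_h2["snp_additive"]
    h_er2 = relative_epistasis_heritability(h_e2, denom, hap_model_id) if denom > 0 else None
    constituents = {f"hap_model_{k}": v for k, v in hap_h2.items()}
    constituents.update({f"snp_model_{k}": v for k, v in snp_h2.items()})
    return EpistasisEstimate(
        h_e2=h_e2,
        h_er2=h_er2,
        hap_model_id=hap_model_id,
        snp_model_id=snp_model_id,
        h_g2=h_g2,
        h_s2=h_s2,
        constituents=constituents,
        haplotype_loss=h_e2 < 0,
    )
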