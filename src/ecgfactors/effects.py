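"""Rendering the morphological effect of a genetic variant on the ECG.

Per-factor effect sizes from the variant scan (estimated on standardized
latents) are transformed back to the original latent scale, added to the
cohort-average latent vector for factors passing a suggestive p-value
filter (default 1e-5), and both latent vectors are decoded; the samplewise
difference is the variant's morphological signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MedianBeat


@dataclass
class VariantEffectProfile:
    """Per-factor effect sizes (original latent scale) and p-values for one
    variant; ``dose`` is the effect-allele count multiplier."""

    variant: str
    effects: np.ndarray     # (K,) per-allele effect on original latent scale
    p_values: np.ndarray    # (K,)
    dose: float = 1.0

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if self.effects.shape != self.p_values.shape or self.effects.ndim != 1:
            raise ValueError("effects and p_values must be equal-length vectors")
        if not np.all(np.isfinite(self.effects)):
            raise ValueError("effects must be finite")
        with np.errstate(invalid="ignore"):
            if np.any((self.p_values < 0) | (self.p_values > 1)):
                raise ValueError("p-values must lie in [0, 1]")

    @classmethod
    def from_scan(cls, scan: pd.DataFrame, variant: str, cohort_sds,
                  dose: float = 1.0) -> "VariantEffectProfile":
        """Build a profile from a variant-scan table (betas on the z scale),
        rescaling to the original latent scale with the cohort factor SDs."""
        rows = scan[scan["variant"] == variant]
        if rows.empty:
            raise KeyError(f"variant {variant!r} not in scan")
        rows = rows.set_index("factor")
        beta_z = rows["beta"].to_numpy(dtype=float)
        p = rows["p"].to_numpy(dtype=float)
        return cls(variant, to_original_scale(beta_z, cohort_sds), p, dose)


def to_original_scale(effects_z, cohort_sds) -> np.ndarray:
    """beta_original_k = beta_z_k * sd_k (undo the per-factor z-scaling)."""
    bz = np.asarray(effects_z, dtype=float)
    sd = np.asarray(cohort_sds, dtype=float)
    if bz.shape != sd.shape:
        raise ValueError("effect and sd vectors must have equal length")
    if np.any(sd <= 0):
        raise ValueError("cohort sds must be positive")
    return bz * sd


def decode_variant_effect(model, mean_latent, profile: VariantEffectProfile,
                          p_threshold: float = 1e-5):
    """(baseline beat, perturbed beat, delta beat) for one variant.

    ``mean_latent`` is the cohort-average latent vector on the original
    scale.  Factors with p >= ``p_threshold`` are filtered out; surviving
    effects are added as ``dose * effect``.  ``model`` is a fitted
    BetaVAEResults whose ``decode`` takes standardized latents.
    """
    mean_latent = np.asarray(mean_latent, dtype=float)
    K = model.config.latent_dim
    if mean_latent.size != K or profile.effects.size != K:
        raise ValueError(f"latent/profile length must equal K={K}")
    keep = profile.p_values < p_threshold
    perturbed = mean_latent + profile.dose * profile.effects * keep

    # decode() expects standardized units; map original-scale vectors in
    z_base = (mean_latent - model.latent_mean) / model.latent_sd
    z_pert = (perturbed - model.latent_mean) / model.latent_sd
    baseline = model.decode(z_base)
    pert_beat = model.decode(z_pert)
    delta = MedianBeat(pert_beat.samples - baseline.samples,
                       baseline.sampling_rate, baseline.r_peak_index)
    return baseline, pert_beat, delta


def render_effect_report(baseline: MedianBeat, perturbed: MedianBeat,
                         delta: MedianBeat, out_dir, variant: str = "variant",
                         lead_layout: tuple = (3, 4)):
    """Write a 12-lead overlay figure and a per-lead max |delta| table.

    Deterministic file output: ``<variant>_overlay.png`` and
    ``<variant>_delta.tsv`` under ``out_dir``.  Returns the delta table.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from pathlib import Path

    if baseline.samples.shape != perturbed.samples.shape:
        raise ValueError("baseline and perturbed beats must share a shape")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    table = pd.DataFrame({
        "lead": list(baseline.lead_names),
        "max_abs_delta_mv": np.max(np.abs(delta.samples), axis=1),
    })
    table.to_csv(out_dir / f"{variant}_delta.tsv", sep="\t", index=False)

    rows, cols = lead_layout
    fig, axes = plt.subplots(rows, cols, figsize=(3 * cols, 2 * rows),
                             sharex=True)
    t = baseline.times * 1000.0
    for i, ax in enumerate(np.ravel(axes)):
        if i >= len(baseline.lead_names):
            ax.axis("off")
            continue
        ax.plot(t, baseline.samples[i], lw=1.0, label="baseline")
        ax.plot(t, perturbed.samples[i], lw=1.0, label="perturbed")
        ax.set_title(baseline.lead_names[i], fontsize=8)
    handles, labels = np.ravel(axes)[0].get_legend_handles_labels()
    fig.legend(handles, labels, loc="lower right", fontsize=8)
    fig.suptitle(f"Morphological effect of {variant}")
    fig.tight_layout()
    fig.savefig(out_dir / f"{variant}_overlay.png", dpi=100)
    plt.close(fig)
    return table
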