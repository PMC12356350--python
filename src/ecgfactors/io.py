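"""Plain-text serialization of beats, cohorts and ground truth.

Beats and rhythm strips are written as whitespace-delimited numeric
matrices (one file per record, one row per lead) with a TSV sidecar holding
sampling rate, R-peak index and lead order.  Phenotype and genotype tables
are TSV; ground-truth generative coefficients are YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import LEAD_NAMES, MedianBeat


def save_beats(beats, out_dir, prefix: str = "beat") -> pd.DataFrame:
    """Write each beat as ``<prefix><i>.txt`` plus a ``<prefix>_meta.tsv``
    sidecar; returns the sidecar table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, b in enumerate(beats):
        name = f"{prefix}{i:05d}.txt"
        np.savetxt(out_dir / name, b.samples, fmt="%.6f")
        rows.append({"file": name, "sampling_rate": b.sampling_rate,
                     "r_peak_index": b.r_peak_index,
                     "leads": ",".join(b.lead_names)})
    meta = pd.DataFrame(rows)
    meta.to_csv(out_dir / f"{prefix}_meta.tsv", sep="\t", index=False)
    return meta


def load_beats(out_dir, prefix: str = "beat") -> list:
    out_dir = Path(out_dir)
    meta = pd.read_csv(out_dir / f"{prefix}_meta.tsv", sep="\t")
    beats = []
    for _, row in meta.iterrows():
        samples = np.loadtxt(out_dir / row["file"])
        leads = tuple(row["leads"].split(","))
        beats.append(MedianBeat(samples, float(row["sampling_rate"]),
                                int(row["r_peak_index"]), leads))
    return beats


def save_truth(truth: dict, path) -> None:
    """Ground-truth coefficients to YAML (plain python scalars only)."""
    def _clean(obj):
        if isinstance(obj, dict):
            return {str(k): _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj
    with open(path, "w") as fh:
        yaml.safe_dump(_clean(truth), fh, sort_keys=True)


def load_truth(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_latents(latents: np.ndarray, path, ids=None) -> None:
    """Latent factors as TSV, columns f1..fK, optional id column."""
    K = latents.shape[1]
    df = pd.DataFrame(latents, columns=[f"f{k + 1}" for k in range(K)])
    if ids is not None:
        df.insert(0, "id", list(ids))
    df.to_csv(path, sep="\t", index=False)


def load_latents(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
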