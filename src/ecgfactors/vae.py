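"""Beta-VAE representation learning on median-beat ECGs.

The model is built statsmodels-style: :class:`BetaVAE` is constructed from a
dataset of median beats plus a :class:`VAEConfig`; ``fit()`` trains with a
90:10 train/validation split and returns a :class:`BetaVAEResults` carrying
the weights of the epoch with the lowest validation loss, the full training
history, and the cohort latent standardization statistics.  Encoding,
decoding, reconstruction QC (Pearson-r threshold 0.7), and factor traversals
(grid -3..+3 in standardized latent units) hang off the results object.

Loss: ``total = reconstruction + beta * KL`` where the reconstruction term
is the QRS-weighted mean squared error over leads x samples (weights
``qrs_weight`` inside the QRS window, 1 elsewhere, normalized by the total
weight) and the KL term is the closed form for a diagonal Gaussian against
the standard normal prior, summed over the K factors.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MedianBeat
from .nn import MLP, Adam
from .preprocess import WeightMask, qrs_weight_mask, qrs_window_from_params


@dataclass
class VAEConfig:
    """Training configuration; every stochastic choice is governed by ``seed``."""

    latent_dim: int = 32
    beta: float = 1e-3
    capacity_max: float = 15.0   # target KL capacity C (nats); 0 disables
    capacity_epochs: int = 30    # C ramps 0 -> capacity_max over these
    capacity_final: float = -1.0  # if >=0, C is squeezed back down to this
    squeeze_epochs: int = 10      # ...over the last squeeze_epochs
    qrs_weight: float = 10.0
    split_fraction: float = 0.9
    max_epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 64
    hidden: tuple = (128, 96)
    downsample: int = 2   # keep every k-th sample before flattening
    pca_components: int = 64  # whitened-PCA encoder frontend; 0 = raw input
    pca_whiten: float = 1.0   # whitening exponent: 1 full, 0 rotation only
    pca_init: bool = False    # initialize as the top-K linear PCA autoencoder
    kl_warmup_epochs: int = 10  # beta ramps 0 -> beta linearly over these
    free_bits: float = 0.0  # per-factor KL floor (nats): no KL gradient below
    sigma_min: float = 0.0  # posterior scale floor; >0 adds denoising pressure
    sigma_min_decay_epochs: int = 0  # release the floor over the last epochs
    lr_decay: bool = True       # cosine-decay learning rate to 5% by the end
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")


def recovery_config(latent_dim: int = 8, seed: int = 0,
                    max_epochs: int = 30) -> VAEConfig:
    """Configuration used for the parameter-recovery study: a K-factor
    model with the whitened-PCA frontend (exponent 0.25) and the
    capacity-annealed objective, sized for CPU training on ~3,000 beats."""
    return VAEConfig(latent_dim=latent_dim, beta=1e-3, capacity_max=35.0,
                     capacity_epochs=max_epochs, max_epochs=max_epochs,
                     batch_size=16, learning_rate=3e-3, hidden=(384, 128),
                     downsample=2, pca_components=64, pca_whiten=0.25,
                     kl_warmup_epochs=0, seed=seed)


def kl_diag_gaussian(mu: np.ndarray, log_var: np.ndarray) -> float:
    """KL( N(mu, diag(sigma^2)) || N(0, I) ) = sum_k 0.5 (mu^2 + s^2 - 1 - ln s^2)."""
    mu = np.asarray(mu, dtype=float)
    log_var = np.asarray(log_var, dtype=float)
    return float(np.sum(0.5 * (mu ** 2 + np.exp(log_var) - 1.0 - log_var)))


def _as_array(beat) -> np.ndarray:
    return beat.samples if isinstance(beat, MedianBeat) else np.asarray(beat, dtype=float)


def elbo_loss(x, x_hat, mu, log_var, weights: WeightMask, beta: float):
    """(total, reconstruction_term, kl_term) for one beat.

    ``reconstruction_term = sum(w * (x - x_hat)^2) / sum(w)`` with the
    per-sample weight vector broadcast across the 12 leads.
    """
    xa, ra = _as_array(x), _as_array(x_hat)
    if xa.shape != ra.shape:
        raise ValueError("x and x_hat shapes differ")
    w = weights.weights
    if w.size != xa.shape[-1]:
        raise ValueError("weight vector length does not match beat length")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ra))
            and np.all(np.isfinite(mu)) and np.all(np.isfinite(log_var))):
        raise ValueError("non-finite inputs to elbo_loss")
    recon = float(np.sum(w * (xa - ra) ** 2) / (xa.shape[0] * np.sum(w)))
    kl = kl_diag_gaussian(mu, log_var)
    return recon + beta * kl, recon, kl


@dataclass
class QCResult:
    """Per-record reconstruction quality against a Pearson-r threshold."""

    table: pd.DataFrame          # columns: record, r, passed, reason
    threshold: float

    @property
    def mean_r(self) -> float:
        return float(self.table["r"].mean())

    @property
    def passed(self) -> np.ndarray:
        return self.table["passed"].to_numpy()

    @property
    def n_excluded(self) -> int:
        return int((~self.table["passed"]).sum())


@dataclass
class Traversal:
    """Decoded beats for one factor varied over a grid, others held at 0."""

    factor_index: int            # 1-based, clinical numbering f1..fK
    grid: np.ndarray
    beats: list

    def summary_stat(self, stat=None) -> np.ndarray:
        """A scalar per grid value (default: signed peak of lead I)."""
        if stat is None:
            stat = lambda b: b.samples[0, np.argmax(np.abs(b.samples[0]))]
        return np.array([stat(b) for b in self.beats])


class BetaVAE:
    """Beta-VAE model over a cohort of equal-length median beats.

    Parameters
    ----------
    beats : sequence of MedianBeat
        Baseline-corrected beats, all with identical shape/sampling rate.
    config : VAEConfig
    qrs_window : (on, off), optional
        Half-open QRS sample window for loss weighting; default a fixed
        100-ms window around the shared R-peak index.
    """

    def __init__(self, beats, config: VAEConfig | None = None,
                 qrs_window: tuple | None = None):
        beats = list(beats)
        if len(beats) < 10:
            raise ValueError("need at least 10 beats to train")
        shape = beats[0].samples.shape
        for b in beats:
            if b.samples.shape != shape:
                raise ValueError("all beats must share one shape")
        self.config = config or VAEConfig()
        self.beats = beats
        self.n_leads, self.n_samples = shape
        self.sampling_rate = beats[0].sampling_rate
        self.r_peak_index = beats[0].r_peak_index
        if qrs_window is None:
            qrs_window = qrs_window_from_params(beats[0])
        self.mask = qrs_weight_mask(self.n_samples, qrs_window,
                                    self.config.qrs_weight)

        ds = self.config.downsample
        self._w_ds = self.mask.weights[::ds].copy()
        self.t_ds = self._w_ds.size
        self.input_dim = self.n_leads * self.t_ds
        self._X = np.stack([b.samples[:, ::ds] for b in beats]).reshape(
            len(beats), self.input_dim)
        # flattened weights, normalized so the weighted MSE matches elbo_loss
        wflat = np.tile(self._w_ds, self.n_leads)
        self._wnorm = wflat / wflat.sum()

    # -- loss over a batch (mean over records) ---------------------------
    def _batch_loss_and_grads(self, F, X, enc: MLP, dec: MLP, rng,
                              beta: float | None = None,
                              capacity: float | None = None,
                              sigma_min: float | None = None):
        """F is the encoder input (whitened features), X the raw target."""
        B = X.shape[0]
        K = self.config.latent_dim
        h, enc_acts = enc.forward(F)
        if sigma_min is None:
            sigma_min = self.config.sigma_min
        lv_lo = 2.0 * np.log(sigma_min) if sigma_min > 0 else -10.0
        mu, log_var = h[:, :K], np.clip(h[:, K:], lv_lo, 10.0)
        eps = rng.standard_normal(mu.shape)
        sigma = np.exp(0.5 * log_var)
        z = mu + sigma * eps
        x_hat, dec_acts = dec.forward(z)

        diff = x_hat - X
        recon = float(np.mean((diff ** 2 * self._wnorm).sum(axis=1)))
        var = np.exp(log_var)
        kl_dims = 0.5 * (mu ** 2 + var - 1.0 - log_var).mean(axis=0)
        kl = float(kl_dims.sum())
        if beta is None:
            beta = self.config.beta
        # capacity-annealed objective: recon + beta * |KL - C|.  With C
        # ramped up over training, high-energy factors are admitted first
        # under full pressure (axis alignment) and weaker morphological
        # factors enter later at no marginal KL cost.
        if capacity is not None:
            kl_term = abs(kl - capacity)
            kl_sign = 1.0 if kl >= capacity else -1.0
        else:
            kl_term = kl
            kl_sign = 1.0
        total = recon + beta * kl_term
        if not np.isfinite(total):
            raise RuntimeError(
                f"training diverged: recon={recon}, kl={kl}; "
                "reduce learning_rate or beta")

        # free bits: factors whose batch KL sits below the floor pay no
        # shrinking KL gradient, so weak directions are not collapsed
        if kl_sign > 0:
            active = (kl_dims > self.config.free_bits).astype(float)
        else:
            active = np.ones_like(kl_dims)

        g_xhat = 2.0 * diff * self._wnorm / B
        g_z, dec_g = dec.backward(dec_acts, g_xhat)
        bks = beta * kl_sign
        g_mu = g_z + bks * active * mu / B
        g_logvar = g_z * (0.5 * sigma * eps) + bks * active * 0.5 * (var - 1.0) / B
        g_logvar[(h[:, K:] < lv_lo) | (h[:, K:] > 10.0)] = 0.0
        g_h = np.concatenate([g_mu, g_logvar], axis=1)
        _, enc_g = enc.backward(enc_acts, g_h)
        return total, recon, kl, enc_g, dec_g

    def _eval_loss(self, F, X, enc: MLP, dec: MLP):
        """Deterministic validation loss: reconstruction at the posterior
        mean plus the KL penalty at the end-of-ramp capacity, so epochs are
        compared on a single fixed objective."""
        K = self.config.latent_dim
        h, _ = enc.forward(F)
        lv_lo = (2.0 * np.log(self.config.sigma_min)
                 if self.config.sigma_min > 0 else -10.0)
        mu, log_var = h[:, :K], np.clip(h[:, K:], lv_lo, 10.0)
        x_hat, _ = dec.forward(mu)
        recon = float(np.mean(((x_hat - X) ** 2 * self._wnorm).sum(axis=1)))
        var = np.exp(log_var)
        kl = float(np.mean(0.5 * (mu ** 2 + var - 1.0 - log_var).sum(axis=1)))
        if self.config.capacity_max > 0:
            c_end = (self.config.capacity_final
                     if self.config.capacity_final >= 0
                     else self.config.capacity_max)
            kl_term = max(kl - c_end, 0.0)
        else:
            kl_term = kl
        return recon + self.config.beta * kl_term, recon, kl

    def fit(self, qc_threshold: float = 0.7) -> "BetaVAEResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        n = self._X.shape[0]
        perm = rng.permutation(n)
        n_train = int(round(cfg.split_fraction * n))
        train_idx, val_idx = perm[:n_train], perm[n_train:]
        if val_idx.size == 0:
            raise ValueError("validation split is empty; lower split_fraction")
        Xtr, Xval = self._X[train_idx], self._X[val_idx]

        # optional whitened-PCA encoder frontend, fitted on the training
        # split: presents every variation direction to the encoder at unit
        # scale, so low-energy morphology (P-wave position, neighbouring-beat
        # intrusion) is not drowned by the QRS.  The decoder still outputs
        # raw samples, so the QRS-weighted loss is unchanged.
        pca = None
        if cfg.pca_components:
            R = int(min(cfg.pca_components, Xtr.shape[0] - 1, self.input_dim))
            from scipy.sparse.linalg import svds
            mean = Xtr.mean(axis=0)
            Xc = Xtr - mean
            v0 = rng.standard_normal(min(Xc.shape))
            _, S, Vt = svds(Xc, k=R, v0=v0)
            order = np.argsort(S)[::-1]
            S, Vt = S[order], Vt[order]
            sd_comp = np.maximum(S / np.sqrt(Xtr.shape[0] - 1), 1e-12)
            # partial whitening: divide by sd^alpha, then rescale so the
            # average feature sd is 1 (alpha=1 full whitening, 0 = rotation)
            scale = sd_comp ** cfg.pca_whiten
            scale = scale * np.mean(sd_comp / scale)
            pca = (mean, Vt.T.copy(), scale)
            Ftr = (Xc @ pca[1]) / scale
            Fval = ((Xval - mean) @ pca[1]) / scale
            enc_in = R
        else:
            Ftr, Fval, enc_in = Xtr, Xval, self.input_dim

        K = cfg.latent_dim
        use_skip = bool(cfg.pca_init and pca is not None)
        enc = MLP([enc_in, *cfg.hidden, 2 * K], rng, skip=use_skip)
        dec = MLP([K, *reversed(cfg.hidden), self.input_dim], rng, skip=use_skip)
        if use_skip:
            # start as the top-K linear PCA autoencoder: mu reads the K
            # highest-variance components (unit-scaled), the decoder paints
            # them back; the nonlinear trunk is shrunk to a perturbation.
            feat_sd = sd_comp / scale
            kk = min(K, enc_in)
            for k in range(kk):
                enc.skip[k, k] = 1.0 / feat_sd[k]
                dec.skip[k, :] = feat_sd[k] * scale[k] * pca[1][:, k]
            dec.biases[-1][:] = mean
            enc.weights[-1] *= 0.1
            dec.weights[-1] *= 0.1
        opt = Adam(enc.params + dec.params, lr=cfg.learning_rate)

        history = []
        best = (np.inf, None, None, -1)
        for epoch in range(cfg.max_epochs):
            # KL warm-up: ramp beta linearly to its target to keep weak
            # morphological directions from collapsing before they are learned
            if cfg.kl_warmup_epochs > 0:
                beta_now = cfg.beta * min(1.0, (epoch + 1) / cfg.kl_warmup_epochs)
            else:
                beta_now = cfg.beta
            if cfg.capacity_max > 0:
                cap_now = cfg.capacity_max * min(
                    1.0, (epoch + 1) / max(cfg.capacity_epochs, 1))
                # squeeze phase: anneal C back down so the code is forced to
                # compress into an efficient, axis-aligned representation
                if cfg.capacity_final >= 0 and cfg.squeeze_epochs > 0:
                    into = epoch - (cfg.max_epochs - cfg.squeeze_epochs)
                    if into >= 0:
                        frac = (into + 1) / cfg.squeeze_epochs
                        cap_now = (cap_now + frac *
                                   (cfg.capacity_final - cap_now))
            else:
                cap_now = None
            if cfg.lr_decay and cfg.max_epochs > 1:
                frac = epoch / (cfg.max_epochs - 1)
                opt.lr = cfg.learning_rate * (0.05 + 0.95 * 0.5 *
                                              (1.0 + math.cos(math.pi * frac)))
            sm_now = cfg.sigma_min
            if cfg.sigma_min > 0 and cfg.sigma_min_decay_epochs > 0:
                into = epoch - (cfg.max_epochs - cfg.sigma_min_decay_epochs)
                if into >= 0:
                    sm_now = cfg.sigma_min * max(
                        0.0, 1.0 - (into + 1) / cfg.sigma_min_decay_epochs)
            order = rng.permutation(n_train)
            tr_tot = 0.0
            for start in range(0, n_train, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                tot, _, _, enc_g, dec_g = self._batch_loss_and_grads(
                    Ftr[idx], Xtr[idx], enc, dec, rng, beta=beta_now,
                    capacity=cap_now, sigma_min=sm_now)
                opt.step(enc_g + dec_g)
                tr_tot += tot * idx.size
            val_tot, val_recon, val_kl = self._eval_loss(Fval, Xval, enc, dec)
            history.append({"epoch": epoch, "train_loss": tr_tot / n_train,
                            "val_loss": val_tot, "val_recon": val_recon,
                            "val_kl": val_kl})
            if val_tot < best[0]:
                best = (val_tot, enc.copy_params(), dec.copy_params(), epoch)

        enc.set_params(best[1])
        dec.set_params(best[2])
        res = BetaVAEResults(
            config=cfg, encoder=enc, decoder=dec,
            history=pd.DataFrame(history), selected_epoch=best[3],
            train_idx=train_idx, val_idx=val_idx, mask=self.mask,
            n_leads=self.n_leads, n_samples_model=self.t_ds,
            sampling_rate=self.sampling_rate / cfg.downsample,
            r_peak_index_model=self.r_peak_index // cfg.downsample,
            downsample=cfg.downsample,
            pca=pca,
        )
        # standardization statistics from training records passing QC
        mu_tr = res._encode_matrix(Xtr)
        qc = res._qc_from_matrix(Xtr, [f"train{i}" for i in range(n_train)],
                                 qc_threshold)
        keep = qc.passed if qc.passed.any() else np.ones(n_train, bool)
        res.latent_mean = mu_tr[keep].mean(axis=0)
        sd = mu_tr[keep].std(axis=0, ddof=0)
        res.latent_sd = np.maximum(sd, 1e-8)
        return res


@dataclass
class BetaVAEResults:
    """Fitted beta-VAE: selected-epoch weights, history, and cohort stats."""

    config: VAEConfig
    encoder: MLP
    decoder: MLP
    history: pd.DataFrame
    selected_epoch: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    mask: WeightMask
    n_leads: int
    n_samples_model: int
    sampling_rate: float
    r_peak_index_model: int
    downsample: int
    pca: tuple | None = None   # (mean, basis d x R, component sds)
    latent_mean: np.ndarray = field(default=None)
    latent_sd: np.ndarray = field(default=None)

    # -- helpers ---------------------------------------------------------
    def _flatten(self, beat) -> np.ndarray:
        x = _as_array(beat)
        ds = self.downsample
        if x.shape == (self.n_leads, self.n_samples_model):
            pass
        elif x.shape[0] == self.n_leads and x[:, ::ds].shape[1] == self.n_samples_model:
            x = x[:, ::ds]
        else:
            raise ValueError(f"beat shape {x.shape} does not match model input")
        return x.reshape(-1)

    def _frontend(self, X: np.ndarray) -> np.ndarray:
        if self.pca is None:
            return X
        mean, basis, scale = self.pca
        return ((X - mean) @ basis) / scale

    def _encode_matrix(self, X: np.ndarray) -> np.ndarray:
        h, _ = self.encoder.forward(self._frontend(X))
        return h[:, :self.config.latent_dim]

    # -- public API ------------------------------------------------------
    def encode(self, beats, standardize: bool = True) -> np.ndarray:
        """Encoder posterior mean mu per beat (no sampling); optionally
        z-transformed with the stored cohort statistics.  Returns (K,) for a
        single beat, (n, K) for a sequence."""
        single = isinstance(beats, MedianBeat) or (
            not isinstance(beats, (list, tuple)))
        items = [beats] if single else list(beats)
        X = np.stack([self._flatten(b) for b in items])
        mu = self._encode_matrix(X)
        if standardize:
            mu = (mu - self.latent_mean) / self.latent_sd
        return mu[0] if single else mu

    def decode(self, z) -> MedianBeat:
        """Deterministic decoded beat (at model resolution) for a latent z
        in standardized units."""
        z = np.asarray(z, dtype=float).reshape(-1)
        if z.size != self.config.latent_dim:
            raise ValueError(
                f"latent vector length {z.size} != K={self.config.latent_dim}")
        z_raw = self.latent_mean + z * self.latent_sd
        x, _ = self.decoder.forward(z_raw[None, :])
        samples = x.reshape(self.n_leads, self.n_samples_model)
        return MedianBeat(samples, self.sampling_rate, self.r_peak_index_model)

    def _qc_from_matrix(self, X, names, threshold) -> QCResult:
        mu = self._encode_matrix(X)
        x_hat, _ = self.decoder.forward(mu)
        rows = []
        for i, name in enumerate(names):
            xi, ri = X[i], x_hat[i]
            if np.std(xi) < 1e-12 or np.std(ri) < 1e-12:
                rows.append({"record": name, "r": np.nan, "passed": False,
                             "reason": "zero-variance signal"})
                continue
            r = float(np.corrcoef(xi, ri)[0, 1])
            rows.append({"record": name, "r": r, "passed": bool(r >= threshold),
                         "reason": "" if r >= threshold else f"r < {threshold}"})
        return QCResult(pd.DataFrame(rows), threshold)

    def reconstruction_qc(self, beats, threshold: float = 0.7,
                          names=None) -> QCResult:
        """Pearson r between each beat and its reconstruction (flattened
        12 x T); records with r below ``threshold`` fail QC."""
        beats = list(beats)
        X = np.stack([self._flatten(b) for b in beats])
        if names is None:
            names = [f"rec{i}" for i in range(len(beats))]
        return self._qc_from_matrix(X, names, threshold)

    def factor_traversal(self, factor_index: int, lo: float = -3.0,
                         hi: float = 3.0, step: float = 1.0) -> Traversal:
        """Decode a grid of values of one factor (1-based index), all other
        factors held at 0 (standardized units)."""
        K = self.config.latent_dim
        if not 1 <= factor_index <= K:
            raise ValueError(f"factor_index must be in 1..{K}")
        grid = np.arange(lo, hi + step / 2, step)
        beats = []
        for v in grid:
            z = np.zeros(K)
            z[factor_index - 1] = v
            beats.append(self.decode(z))
        return Traversal(factor_index, grid, beats)

    def latent_variances(self, beats=None) -> np.ndarray:
        """Unstandardized per-factor variance over a cohort (training-set
        statistics when no beats are given)."""
        if beats is None:
            return self.latent_sd ** 2
        mu = self.encode(beats, standardize=False)
        return mu.var(axis=0, ddof=0)

    def summary(self) -> str:
        cfg = self.config
        sel = self.history.iloc[self.selected_epoch]
        collapsed = int((self.latent_sd ** 2 < 1e-3).sum())
        buf = io.StringIO()
        buf.write("Beta-VAE results\n")
        buf.write("=" * 50 + "\n")
        buf.write(f"latent factors (K)     {cfg.latent_dim}\n")
        buf.write(f"beta                   {cfg.beta}\n")
        buf.write(f"qrs weight             {cfg.qrs_weight}\n")
        buf.write(f"input                  {self.n_leads} x {self.n_samples_model} "
                  f"(downsample {self.downsample})\n")
        buf.write(f"records train/val      {self.train_idx.size}/{self.val_idx.size}\n")
        buf.write(f"epochs run             {len(self.history)}\n")
        buf.write(f"selected epoch         {self.selected_epoch} "
                  f"(val loss {sel['val_loss']:.6g})\n")
        buf.write(f"val recon / KL         {sel['val_recon']:.6g} / {sel['val_kl']:.6g}\n")
        buf.write(f"factors with var<1e-3  {collapsed}\n")
        return buf.getvalue()

    # -- serialization ---------------------------------------------------
    def save(self, path) -> None:
        enc_k = len(self.encoder.weights)
        dec_k = len(self.decoder.weights)
        arrays = {f"enc_{i}": p for i, p in enumerate(self.encoder.params)}
        arrays.update({f"dec_{i}": p for i, p in enumerate(self.decoder.params)})
        np.savez(
            path, **arrays,
            enc_sizes=np.array(self.encoder.sizes), enc_k=enc_k,
            dec_sizes=np.array(self.decoder.sizes), dec_k=dec_k,
            latent_mean=self.latent_mean, latent_sd=self.latent_sd,
            mask_weights=self.mask.weights,
            mask_window=np.array(self.mask.qrs_window),
            train_idx=self.train_idx, val_idx=self.val_idx,
            selected_epoch=self.selected_epoch,
            history=self.history.to_numpy(),
            history_cols=np.array([str(c) for c in self.history.columns]),
            meta=np.array([self.n_leads, self.n_samples_model,
                           self.sampling_rate, self.r_peak_index_model,
                           self.downsample], dtype=float),
            config=np.array([self.config.latent_dim, self.config.beta,
                             self.config.qrs_weight, self.config.split_fraction,
                             self.config.max_epochs, self.config.learning_rate,
                             self.config.batch_size, self.config.downsample,
                             self.config.seed, self.config.pca_components,
                             self.config.kl_warmup_epochs,
                             float(self.config.lr_decay),
                             self.config.pca_whiten,
                             self.config.capacity_max,
                             self.config.capacity_epochs,
                             self.config.free_bits,
                             float(self.config.pca_init)], dtype=float),
            hidden=np.array(self.config.hidden, dtype=float),
            has_pca=np.array(self.pca is not None),
            **({"pca_mean": self.pca[0], "pca_basis": self.pca[1],
                "pca_scale": self.pca[2]} if self.pca is not None else {}),
        )

    @staticmethod
    def load(path) -> "BetaVAEResults":
        d = np.load(path, allow_pickle=False)
        c = d["config"]
        cfg = VAEConfig(latent_dim=int(c[0]), beta=float(c[1]),
                        qrs_weight=float(c[2]), split_fraction=float(c[3]),
                        max_epochs=int(c[4]), learning_rate=float(c[5]),
                        batch_size=int(c[6]), downsample=int(c[7]),
                        seed=int(c[8]), pca_components=int(c[9]),
                        kl_warmup_epochs=int(c[10]), lr_decay=bool(c[11]),
                        pca_whiten=float(c[12]), capacity_max=float(c[13]),
                        capacity_epochs=int(c[14]), free_bits=float(c[15]),
                        pca_init=bool(c[16]),
                        hidden=tuple(int(h) for h in d["hidden"]))
        rng = np.random.default_rng(0)
        use_skip = cfg.pca_init and bool(d["has_pca"])
        enc = MLP([int(s) for s in d["enc_sizes"]], rng, skip=use_skip)
        dec = MLP([int(s) for s in d["dec_sizes"]], rng, skip=use_skip)
        enc.set_params([d[f"enc_{i}"] for i in range(len(enc.params))])
        dec.set_params([d[f"dec_{i}"] for i in range(len(dec.params))])
        mw = d["mask_weights"]
        window = tuple(int(v) for v in d["mask_window"])
        mask = WeightMask(mw, window, cfg.qrs_weight)
        meta = d["meta"]
        res = BetaVAEResults(
            config=cfg, encoder=enc, decoder=dec,
            history=pd.DataFrame(d["history"],
                                 columns=[str(x) for x in d["history_cols"]]),
            selected_epoch=int(d["selected_epoch"]),
            train_idx=d["train_idx"], val_idx=d["val_idx"], mask=mask,
            n_leads=int(meta[0]), n_samples_model=int(meta[1]),
            sampling_rate=float(meta[2]), r_peak_index_model=int(meta[3]),
            downsample=int(meta[4]),
            pca=((d["pca_mean"], d["pca_basis"], d["pca_scale"])
                 if bool(d["has_pca"]) else None),
            latent_mean=d["latent_mean"], latent_sd=d["latent_sd"],
        )
        return res
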