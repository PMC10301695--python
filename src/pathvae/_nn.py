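"""NumPy implementation of the masked variational autoencoder.

The architecture is small and fixed — a one-hidden-layer non-linear encoder and
a linear, sparse, skip-concatenated decoder — so the forward and backward passes
are written out explicitly.  All stochasticity (init, dropout, reparameterization
noise, batching) flows through seeded ``numpy.random.Generator`` instances, which
makes training bit-reproducible on a single CPU.

Decoder weights obey two hard constraints that are re-imposed after every
optimizer step: non-negativity (activities keep a direction) and exact zeros at
positions where the ontology has no edge or annotation (the binary masks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MaskedVAE", "AdamW", "kl_closed_form", "LossReport"]


def kl_closed_form(mu: np.ndarray, log_var: np.ndarray) -> float:
    """KL divergence of a diagonal Gaussian from the standard normal prior.

    ``sum_i 0.5 * (mu_i^2 + sigma_i^2 - 1 - log sigma_i^2)``, summed over all
    entries of the input arrays.
    """
    mu = np.asarray(mu, dtype=float)
    log_var = np.asarray(log_var, dtype=float)
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(log_var))):
        raise FloatingPointError("non-finite input to kl_closed_form")
    return float(0.5 * np.sum(mu ** 2 + np.exp(log_var) - 1.0 - log_var))


@dataclass
class LossReport:
    """ELBO components for one batch (sign convention: loss is minimized).

    ``elbo_objective`` is the evidence lower bound under the implemented
    convention: ``-(reconstruction_term) - kl_weight * kl_term``, where
    ``reconstruction_term`` is the Gaussian reconstruction loss (mean over
    samples of the summed squared error, i.e. -log likelihood up to an additive
    constant) and ``kl_term`` the closed-form KL per sample.
    """

    reconstruction_term: float
    kl_term: float
    kl_weight: float

    @property
    def elbo_objective(self) -> float:
        return -self.reconstruction_term - self.kl_weight * self.kl_term

    @property
    def total_loss(self) -> float:
        return self.reconstruction_term + self.kl_weight * self.kl_term


class MaskedVAE:
    """Parameters + forward/backward of the ontology-masked VAE.

    Parameters
    ----------
    masks
        Decoder connectivity: one ``(k*|layer d|, k*|layers<d|)`` matrix per
        decoder depth ``1..D``, then the ``(n_genes, k*n_terms)`` reconstruction
        mask (the output of ``ontology.build_masks``).
    n_genes, latent_dim, hidden
        Input width, ``k * |depth-0 terms|``, encoder hidden width.
    """

    def __init__(self, masks: list[np.ndarray], n_genes: int, latent_dim: int,
                 hidden: int, rng: np.random.Generator,
                 dropout_hidden: float = 0.2, dropout_latent: float = 0.5):
        if latent_dim < 1:
            raise ValueError("empty depth-0 layer: latent dimension must be >= 1")
        self.dec_masks = [np.asarray(m, dtype=float) for m in masks[:-1]]
        self.recon_mask = np.asarray(masks[-1], dtype=float)
        self.n_genes = n_genes
        self.latent_dim = latent_dim
        self.dropout_hidden = dropout_hidden
        self.dropout_latent = dropout_latent
        self.layer_widths = [latent_dim] + [m.shape[0] for m in self.dec_masks]

        expected_cols = np.cumsum([latent_dim] + [m.shape[0] for m in self.dec_masks])
        for d, m in enumerate(self.dec_masks, start=1):
            if m.shape[1] != expected_cols[d - 1]:
                raise ValueError(f"decoder mask {d} has {m.shape[1]} columns, expected {expected_cols[d-1]}")
        if self.recon_mask.shape != (n_genes, expected_cols[-1]):
            raise ValueError("reconstruction mask shape mismatch")

        p: dict[str, np.ndarray] = {}
        p["W1"] = rng.normal(0.0, 1.0 / np.sqrt(n_genes), (n_genes, hidden))
        p["b1"] = np.zeros(hidden)
        p["Wm"] = rng.normal(0.0, 1.0 / np.sqrt(hidden), (hidden, latent_dim))
        p["bm"] = np.zeros(latent_dim)
        p["Wv"] = rng.normal(0.0, 1.0 / np.sqrt(hidden), (hidden, latent_dim))
        p["bv"] = np.zeros(latent_dim)
        # non-negative decoder init: |N(0, 1/sqrt(fan_in))| restricted to the mask
        for d, m in enumerate(self.dec_masks, start=1):
            fan_in = max(1.0, m.sum(axis=1).max())
            p[f"Wd{d}"] = np.abs(rng.normal(0.0, 1.0 / np.sqrt(fan_in), m.shape)) * m
            p[f"bd{d}"] = np.zeros(m.shape[0])
        fan_in = max(1.0, self.recon_mask.sum(axis=1).max())
        p["Wr"] = np.abs(rng.normal(0.0, 1.0 / np.sqrt(fan_in), self.recon_mask.shape)) * self.recon_mask
        p["br"] = np.zeros(n_genes)
        self.params = p

    # ---- constraint projection ------------------------------------------

    def project_decoder(self) -> None:
        """Clamp decoder weights to >= 0 and zero out masked positions."""
        for d, m in enumerate(self.dec_masks, start=1):
            np.maximum(self.params[f"Wd{d}"], 0.0, out=self.params[f"Wd{d}"])
            self.params[f"Wd{d}"] *= m
        np.maximum(self.params["Wr"], 0.0, out=self.params["Wr"])
        self.params["Wr"] *= self.recon_mask

    def decoder_weight_names(self) -> list[str]:
        return [f"Wd{d}" for d in range(1, len(self.dec_masks) + 1)] + ["Wr"]

    # ---- encoder / decoder ----------------------------------------------

    def encode(self, X: np.ndarray, rng: np.random.Generator | None = None,
               training: bool = False) -> dict:
        p = self.params
        h_pre = X @ p["W1"] + p["b1"]
        h = np.maximum(h_pre, 0.0)
        if training:
            keep = 1.0 - self.dropout_hidden
            m1 = (rng.random(h.shape) < keep) / keep
            hd = h * m1
        else:
            m1 = None
            hd = h
        mu = hd @ p["Wm"] + p["bm"]
        log_var = hd @ p["Wv"] + p["bv"]
        return {"X": X, "h_pre": h_pre, "h": h, "m1": m1, "hd": hd, "mu": mu, "log_var": log_var}

    def decode(self, z: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """Linear masked decoding of latent codes ``z`` (batch x latent_dim).

        Returns the per-layer term activations (layer 0 is ``z`` itself) and the
        gene reconstruction.  NaNs raise, naming the first offending layer.
        """
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[1] != self.latent_dim:
            raise ValueError(f"z has {z.shape[1]} columns, expected {self.latent_dim}")
        p = self.params
        outs = [z]
        for d, m in enumerate(self.dec_masks, start=1):
            c = np.concatenate(outs, axis=1)
            out = c @ (p[f"Wd{d}"] * m).T + p[f"bd{d}"]
            if not np.all(np.isfinite(out)):
                raise FloatingPointError(f"non-finite values in decoder layer {d}")
            outs.append(out)
        c_all = np.concatenate(outs, axis=1)
        recon = c_all @ (p["Wr"] * self.recon_mask).T + p["br"]
        if not np.all(np.isfinite(recon)):
            raise FloatingPointError("non-finite values in reconstruction layer")
        return outs, recon

    # ---- training forward/backward --------------------------------------

    def forward(self, X: np.ndarray, kl_weight: float,
                rng: np.random.Generator | None = None, training: bool = False) -> tuple[LossReport, dict]:
        """Full pass: encode, reparameterize, decode, loss.  Returns cache for backward."""
        B = X.shape[0]
        cache = self.encode(X, rng, training)
        mu, log_var = cache["mu"], cache["log_var"]
        if training:
            eps = rng.standard_normal(mu.shape)
            z = mu + np.exp(0.5 * log_var) * eps
            keep = 1.0 - self.dropout_latent
            mz = (rng.random(z.shape) < keep) / keep
            zd = z * mz
        else:
            eps = None
            mz = None
            zd = mu
        outs, recon = self.decode(zd)
        cache.update(eps=eps, mz=mz, zd=zd, outs=outs, recon=recon, training=training)
        recon_loss = float(np.sum((recon - X) ** 2)) / B
        kl = kl_closed_form(mu, log_var) / B
        return LossReport(recon_loss, kl, kl_weight), cache

    def backward(self, cache: dict, kl_weight: float) -> dict[str, np.ndarray]:
        """Exact gradients of ``total_loss`` w.r.t. every parameter."""
        p = self.params
        X = cache["X"]
        B = X.shape[0]
        outs = cache["outs"]
        c_all = np.concatenate(outs, axis=1)
        grads: dict[str, np.ndarray] = {}

        d_recon = 2.0 * (cache["recon"] - X) / B
        grads["Wr"] = (d_recon.T @ c_all) * self.recon_mask
        grads["br"] = d_recon.sum(axis=0)
        d_c_all = d_recon @ (p["Wr"] * self.recon_mask)

        # split the concatenated gradient back into per-layer pieces
        widths = self.layer_widths
        offsets = np.cumsum([0] + widths)
        d_outs = [d_c_all[:, offsets[i]:offsets[i + 1]].copy() for i in range(len(widths))]

        for d in range(len(self.dec_masks), 0, -1):
            m = self.dec_masks[d - 1]
            c_d = np.concatenate(outs[:d], axis=1)
            d_out = d_outs[d]
            grads[f"Wd{d}"] = (d_out.T @ c_d) * m
            grads[f"bd{d}"] = d_out.sum(axis=0)
            d_c = d_out @ (p[f"Wd{d}"] * m)
            for i in range(d):
                d_outs[i] += d_c[:, offsets[i]:offsets[i + 1]]

        d_zd = d_outs[0]
        mu, log_var = cache["mu"], cache["log_var"]
        if cache["training"]:
            d_z = d_zd * cache["mz"]
            d_mu = d_z.copy()
            d_lv = d_z * cache["eps"] * 0.5 * np.exp(0.5 * log_var)
        else:
            d_mu = d_zd.copy()
            d_lv = np.zeros_like(log_var)
        # KL gradient (closed form, averaged over the batch)
        d_mu += kl_weight * mu / B
        d_lv += kl_weight * 0.5 * (np.exp(log_var) - 1.0) / B

        hd = cache["hd"]
        grads["Wm"] = hd.T @ d_mu
        grads["bm"] = d_mu.sum(axis=0)
        grads["Wv"] = hd.T @ d_lv
        grads["bv"] = d_lv.sum(axis=0)
        d_hd = d_mu @ p["Wm"].T + d_lv @ p["Wv"].T
        d_h = d_hd * cache["m1"] if cache["training"] else d_hd
        d_h_pre = d_h * (cache["h_pre"] > 0)
        grads["W1"] = X.T @ d_h_pre
        grads["b1"] = d_h_pre.sum(axis=0)
        return grads


class AdamW:
    """AdamW with decoupled weight decay (decay on weight matrices, not biases)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            if self.weight_decay and k.startswith("W"):
                update = update + self.weight_decay * params[k]
            params[k] -= self.lr * update
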