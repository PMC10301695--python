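"""Model and results objects for the ontology-guided VAE.

Usage follows the model/results pattern of statistical modelling packages::

    onto = TrimmedOntology.load("ontology.json")
    model = OntologyVAE(expression_df, onto)      # aligns genes, builds network
    res = model.fit(seed=0)                       # trains, keeps best-epoch weights
    print(res.summary())
    act = res.activities(expression_df)           # samples x terms pathway activities

The encoder is a one-hidden-layer non-linear network producing a diagonal
Gaussian posterior q(z|x); the decoder is linear, sparse (ontology-masked) and
non-negative, with skip concatenation so a term can feed any deeper layer and
the gene reconstruction layer.  The objective is the evidence lower bound with
a Gaussian reconstruction likelihood (mean squared error) and a closed-form KL
term weighted by ``kl_weight``.
"""

from __future__ import annotations

import io
import json
import logging
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._nn import AdamW, LossReport, MaskedVAE, kl_closed_form
from .ontology import TrimmedOntology, compile_ontology

logger = logging.getLogger(__name__)

__all__ = ["ModelSpec", "OntologyVAE", "OntologyVAEResults", "align_genes",
           "kl_closed_form", "LossReport"]

_CHECKPOINT_VERSION = 1


@dataclass
class ModelSpec:
    """Hyperparameters of the ontology VAE.

    Defaults follow the published training protocol: batch size 128, encoder
    hidden dropout 0.2, latent dropout 0.5, KL weight 1e-4, AdamW with learning
    rate 1e-4, up to 300 epochs, 80/20 train/validation split, three neurons
    per ontology term.
    """

    neurons_per_term: int = 3
    encoder_hidden_width: int = 512
    dropout_hidden: float = 0.2
    dropout_latent: float = 0.5
    kl_weight: float = 1e-4
    learning_rate: float = 1e-4
    weight_decay: float = 0.01
    batch_size: int = 128
    max_epochs: int = 300
    validation_fraction: float = 0.2
    seed: int = 0
    input_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.neurons_per_term < 1:
            raise ValueError("neurons_per_term must be >= 1")
        for name in ("dropout_hidden", "dropout_latent"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be >= 0")


def align_genes(data, genes: list[str]) -> np.ndarray:
    """Align a samples x genes table to the ontology gene order.

    Missing ontology genes are zero-filled; extra data genes are dropped; both
    counts are logged.  A DataFrame is aligned by column name; a bare array must
    already have ``len(genes)`` columns.
    """
    if isinstance(data, pd.DataFrame):
        present = [g for g in genes if g in data.columns]
        missing = len(genes) - len(present)
        extra = data.shape[1] - len(present)
        if not present:
            raise ValueError("no overlap between data genes and ontology genes")
        if missing or extra:
            logger.info("align_genes: %d ontology genes zero-filled, %d data genes dropped",
                        missing, extra)
        out = np.zeros((data.shape[0], len(genes)))
        idx = {g: i for i, g in enumerate(genes)}
        for g in present:
            out[:, idx[g]] = data[g].to_numpy(dtype=float)
        return out
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(genes):
        raise ValueError(f"array data must have {len(genes)} columns (ontology gene order)")
    return arr


class OntologyVAE:
    """Ontology-guided VAE bound to a dataset.

    Parameters
    ----------
    data
        samples x genes expression (DataFrame with gene columns, or array in
        ontology gene order); log-scale non-negative continuous values.
    ontology
        A :class:`~pathvae.ontology.TrimmedOntology`; masks are (re)compiled for
        ``spec.neurons_per_term`` if needed.
    spec
        :class:`ModelSpec`; keyword overrides are applied on top.
    """

    def __init__(self, data, ontology: TrimmedOntology, spec: ModelSpec | None = None, **overrides):
        spec = spec or ModelSpec()
        for k, v in overrides.items():
            if not hasattr(spec, k):
                raise TypeError(f"unknown hyperparameter {k!r}")
            setattr(spec, k, v)
        spec.__post_init__()
        spec.input_genes = list(ontology.genes)
        if ontology.neurons_per_term != spec.neurons_per_term or not ontology.masks:
            compile_ontology(ontology, spec.neurons_per_term)
        if not ontology.root_terms:
            raise ValueError("ontology has no depth-0 terms; latent space would be empty")
        self.spec = spec
        self.ontology = ontology
        if isinstance(data, pd.DataFrame):
            self.sample_ids = list(data.index)
        else:
            self.sample_ids = list(range(np.asarray(data).shape[0]))
        self.exog = align_genes(data, ontology.genes)
        if self.exog.shape[0] < 2:
            raise ValueError("need at least 2 samples")

    # ------------------------------------------------------------------

    def _build_net(self, seed: int) -> MaskedVAE:
        k = self.spec.neurons_per_term
        return MaskedVAE(
            self.ontology.masks,
            n_genes=len(self.ontology.genes),
            latent_dim=k * len(self.ontology.root_terms),
            hidden=self.spec.encoder_hidden_width,
            rng=np.random.default_rng(seed),
            dropout_hidden=self.spec.dropout_hidden,
            dropout_latent=self.spec.dropout_latent,
        )

    def fit(self, seed: int | None = None, max_epochs: int | None = None,
            on_epoch_end=None, verbose: bool = False) -> "OntologyVAEResults":
        """Train with AdamW and return the best-validation-epoch results.

        The sample set is split 80/20 by a seeded uniform permutation.  After
        every optimizer step the decoder weights are clamped to be non-negative
        and masked positions reset to exactly zero.  Ties on the validation loss
        resolve to the earliest epoch.

        ``on_epoch_end(epoch, net, history_row)`` is called after each epoch —
        useful for monitoring or invariant checks.
        """
        spec = self.spec
        seed = spec.seed if seed is None else seed
        n_epochs = spec.max_epochs if max_epochs is None else max_epochs
        rng = np.random.default_rng(seed + 1)

        n = self.exog.shape[0]
        n_val = int(round(spec.validation_fraction * n))
        if n_val == 0 or n_val == n:
            raise ValueError("validation split empty; adjust validation_fraction or sample size")
        perm = rng.permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        X_train, X_val = self.exog[train_idx], self.exog[val_idx]

        net = self._build_net(seed)
        opt = AdamW(net.params, lr=spec.learning_rate, weight_decay=spec.weight_decay)

        history: list[dict] = []
        best_val = np.inf
        best_epoch = -1
        best_params = {k: v.copy() for k, v in net.params.items()}
        for epoch in range(n_epochs):
            order = rng.permutation(len(train_idx))
            for start in range(0, len(order), spec.batch_size):
                batch = X_train[order[start:start + spec.batch_size]]
                report, cache = net.forward(batch, spec.kl_weight, rng, training=True)
                if not np.isfinite(report.total_loss):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch}")
                grads = net.backward(cache, spec.kl_weight)
                opt.step(net.params, grads)
                net.project_decoder()
            train_report, _ = net.forward(X_train, spec.kl_weight, training=False)
            val_report, _ = net.forward(X_val, spec.kl_weight, training=False)
            row = {"epoch": epoch, "train_loss": train_report.total_loss,
                   "val_loss": val_report.total_loss}
            history.append(row)
            if verbose:
                logger.info("epoch %d train %.4f val %.4f", epoch, row["train_loss"], row["val_loss"])
            if row["val_loss"] < best_val:
                best_val = row["val_loss"]
                best_epoch = epoch
                best_params = {k: v.copy() for k, v in net.params.items()}
            if on_epoch_end is not None:
                on_epoch_end(epoch, net, row)

        net.params = best_params
        return OntologyVAEResults(
            model=self,
            net=net,
            history=pd.DataFrame(history),
            best_epoch=best_epoch,
            fit_seed=seed,
        )

    def init_model(self, seed: int | None = None) -> "OntologyVAEResults":
        """An untrained results object (random initial weights); mainly for tests."""
        seed = self.spec.seed if seed is None else seed
        return OntologyVAEResults(model=self, net=self._build_net(seed),
                                  history=pd.DataFrame(), best_epoch=-1, fit_seed=seed,
                                  trained=False)


class OntologyVAEResults:
    """Fitted (or initialized) ontology VAE: weights, history, and readouts."""

    def __init__(self, model: OntologyVAE, net: MaskedVAE, history: pd.DataFrame,
                 best_epoch: int, fit_seed: int, trained: bool = True):
        self.model = model
        self.spec = model.spec
        self.ontology = model.ontology
        self.net = net
        self.history = history
        self.best_epoch = best_epoch
        self.fit_seed = fit_seed
        self.trained = trained

    # ---- readouts (delegated) ----------------------------------------

    def activities(self, data=None) -> "pd.DataFrame":
        from .activity import get_activities
        return get_activities(self, self.model.exog if data is None else data).to_frame()

    def reconstruction(self, data=None) -> "pd.DataFrame":
        from .activity import get_reconstruction
        return get_reconstruction(self, self.model.exog if data is None else data).to_frame()

    def decode(self, z: np.ndarray):
        """Per-layer term activations and gene reconstruction for latent codes."""
        return self.net.decode(z)

    def elbo(self, data=None, seed: int | None = None, training: bool = False) -> LossReport:
        """ELBO components on a data batch (deterministic when ``training=False``)."""
        X = self.model.exog if data is None else align_genes(data, self.ontology.genes)
        rng = np.random.default_rng(self.fit_seed if seed is None else seed)
        report, _ = self.net.forward(X, self.spec.kl_weight, rng, training=training)
        return report

    def perturb(self, gene: str, mode: str = "knockout", value: float | None = None,
                data=None, **kwargs):
        """Single-gene in-silico perturbation analysis at every term and gene.

        Thin wrapper over :func:`pathvae.perturbation.term_and_gene_level_analysis`.
        """
        from .perturbation import Perturbation, term_and_gene_level_analysis
        X = self.model.exog if data is None else data
        return term_and_gene_level_analysis(self, X, Perturbation(gene, mode, value), **kwargs)

    # ---- diagnostics --------------------------------------------------

    def summary(self) -> str:
        o = self.ontology
        lines = [
            "Ontology-guided VAE results",
            "=" * 40,
            f"terms kept:           {len(o.kept_terms)}",
            f"decoder layers:       {o.max_depth} (+ reconstruction)",
            f"depth-0 (latent) terms: {len(o.root_terms)}",
            f"genes:                {len(o.genes)}",
            f"neurons per term:     {self.spec.neurons_per_term}",
            f"latent dimension:     {self.net.latent_dim}",
            f"encoder hidden width: {self.spec.encoder_hidden_width}",
            f"trained:              {self.trained}",
        ]
        if self.trained and len(self.history):
            best = self.history.iloc[self.best_epoch]
            lines += [
                f"epochs run:           {len(self.history)}",
                f"best epoch:           {self.best_epoch}",
                f"best val loss:        {best['val_loss']:.6g}",
                f"train loss at best:   {best['train_loss']:.6g}",
            ]
        return "\n".join(lines)

    # ---- persistence --------------------------------------------------

    def save(self, path) -> None:
        """Single-archive checkpoint: JSON metadata + raw weight arrays."""
        meta = {
            "format": "pathvae-checkpoint",
            "version": _CHECKPOINT_VERSION,
            "spec": asdict(self.spec),
            "ontology_hash": self.ontology.content_hash(),
            "ontology": self.ontology.to_dict(),
            "best_epoch": int(self.best_epoch),
            "fit_seed": int(self.fit_seed),
            "trained": bool(self.trained),
            "history": self.history.to_dict(orient="list"),
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            buf = io.BytesIO()
            np.savez(buf, **self.net.params)
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path, ontology: TrimmedOntology | None = None) -> "OntologyVAEResults":
        """Load a checkpoint; decode outputs are bit-identical to pre-save.

        If ``ontology`` is given, its content hash must match the one stored in
        the checkpoint; otherwise the embedded ontology is reconstructed.
        """
        try:
            with zipfile.ZipFile(path) as zf:
                meta = json.loads(zf.read("meta.json"))
                with zf.open("weights.npz") as fh:
                    weights = dict(np.load(io.BytesIO(fh.read())))
        except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
            raise ValueError(f"unreadable or truncated checkpoint {path}: {exc}") from exc
        if meta.get("format") != "pathvae-checkpoint" or meta.get("version") != _CHECKPOINT_VERSION:
            raise ValueError("checkpoint version mismatch")
        if ontology is not None:
            if ontology.content_hash() != meta["ontology_hash"]:
                raise ValueError("ontology hash mismatch: checkpoint was built from a different ontology")
            onto = ontology
        else:
            onto = TrimmedOntology.from_dict(meta["ontology"])
        spec_d = dict(meta["spec"])
        spec = ModelSpec(**spec_d)
        if onto.neurons_per_term != spec.neurons_per_term or not onto.masks:
            compile_ontology(onto, spec.neurons_per_term)
        # rebuild a model shell bound to a placeholder dataset of correct width
        shell = OntologyVAE.__new__(OntologyVAE)
        shell.spec = spec
        shell.ontology = onto
        shell.exog = np.zeros((2, len(onto.genes)))
        shell.sample_ids = [0, 1]
        net = MaskedVAE(onto.masks, len(onto.genes),
                        spec.neurons_per_term * len(onto.root_terms),
                        spec.encoder_hidden_width, np.random.default_rng(0),
                        spec.dropout_hidden, spec.dropout_latent)
        net.params = {k: np.asarray(v) for k, v in weights.items()}
        return cls(model=shell, net=net,
                   history=pd.DataFrame(meta.get("history", {})),
                   best_epoch=meta["best_epoch"], fit_seed=meta["fit_seed"],
                   trained=meta["trained"])


# ---- spec-level functional aliases ---------------------------------------

def save_model(results: OntologyVAEResults, path) -> None:
    results.save(path)


def load_model(path, ontology: TrimmedOntology | None = None) -> OntologyVAEResults:
    return OntologyVAEResults.load(path, ontology)
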