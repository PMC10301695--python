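"""Pathway-activity and reconstruction readouts from a trained model.

A sample's *activity* at an ontology term is the activation of that term's
neuron group when the sample is run through the model, averaged over the
``k`` neurons per term.  Inference is deterministic: the encoder's posterior
mean μ is used instead of a sampled z and all dropout is disabled, so repeated
calls are bit-identical.  Depth-0 (latent) terms therefore report averaged μ
components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import OntologyVAEResults, align_genes

logger = logging.getLogger(__name__)

__all__ = ["ActivityMatrix", "get_activities", "get_reconstruction"]


@dataclass
class ActivityMatrix:
    """samples x columns activity table; columns are terms or genes."""

    values: np.ndarray
    column_ids: list[str]
    sample_ids: list
    source: str  # "terms" | "genes"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.column_ids)
        df.attrs["source"] = self.source
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample")


def _forward_deterministic(results: OntologyVAEResults, data) -> tuple[np.ndarray, np.ndarray, list]:
    if not results.trained:
        warnings.warn("model has not been trained; activities come from initial weights")
    onto = results.ontology
    if isinstance(data, pd.DataFrame):
        sample_ids = list(data.index)
    else:
        sample_ids = list(range(np.asarray(data).shape[0]))
    X = align_genes(data, onto.genes)
    cache = results.net.encode(X, training=False)
    outs, recon = results.net.decode(cache["mu"])
    c_all = np.concatenate(outs, axis=1)  # kept_terms order, k neurons per term
    return c_all, recon, sample_ids


def get_activities(results: OntologyVAEResults, data) -> ActivityMatrix:
    """Per-sample activities for every kept term (k-neuron averages)."""
    onto = results.ontology
    k = onto.neurons_per_term
    c_all, _, sample_ids = _forward_deterministic(results, data)
    n_terms = len(onto.kept_terms)
    values = c_all.reshape(c_all.shape[0], n_terms, k).mean(axis=2)
    return ActivityMatrix(values, list(onto.kept_terms), sample_ids, "terms")


def get_reconstruction(results: OntologyVAEResults, data) -> ActivityMatrix:
    """Per-sample reconstruction-layer readout for every gene."""
    onto = results.ontology
    _, recon, sample_ids = _forward_deterministic(results, data)
    return ActivityMatrix(recon, list(onto.genes), sample_ids, "genes")
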