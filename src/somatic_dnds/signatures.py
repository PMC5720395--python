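"""Mutational-signature exposure estimation and hypermutator classification.

A sample's 96-channel trinucleotide spectrum is decomposed over a fixed
signature matrix by expectation-maximization under a multinomial mixture:
each mutation is attributed fractionally to signatures in the E-step and the
exposure vector c is re-estimated in the M-step, until the L1 change of c
falls below tolerance.  Hypermutator samples (by default > 1,000 coding
substitutions) are labelled by their dominant mutational process when one
signature (or a merged group such as the two APOBEC signatures) explains more
than half of the mutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PYRIMIDINES = "CT"
SUBSTITUTION_TYPES = [("C", "A"), ("C", "G"), ("C", "T"),
                      ("T", "A"), ("T", "C"), ("T", "G")]
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# Canonical pyrimidine-centric channel order: 6 substitution types x 16
# contexts, contexts ordered by upstream then downstream base (A, C, G, T).
CHANNELS_96 = [f"{up}[{ref}>{alt}]{down}"
               for (ref, alt) in SUBSTITUTION_TYPES
               for up in "ACGT" for down in "ACGT"]
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}

# Dominant-process labels for the classical COSMIC v2 signatures used in
# hypermutator classification; signatures 2 and 13 are merged as APOBEC.
DEFAULT_SIGNATURE_LABELS = {"2": "APOBEC", "13": "APOBEC", "4": "smoking",
                            "6": "MMR", "7": "UV", "10": "POLE"}
NOT_HYPERMUTATOR = "not_hypermutator"


class SignatureError(ValueError):
    pass


def channel_of(up: str, ref: str, alt: str, down: str) -> int:
    """96-channel index of a substitution, folding purine refs onto pyrimidines."""
    if ref not in PYRIMIDINES:
        up, ref, alt, down = _COMP[down], _COMP[ref], _COMP[alt], _COMP[up]
    return _CHANNEL_INDEX[f"{up}[{ref}>{alt}]{down}"]


@dataclass
class SignatureMatrix:
    """Signatures x 96 channel probabilities; rows sum to 1."""
    probabilities: np.ndarray
    names: list

    def __post_init__(self):
        P = np.asarray(self.probabilities, dtype=float)
        if P.ndim != 2 or P.shape[1] != 96:
            raise SignatureError("signature matrix must be S x 96")
        if (P < 0).any():
            raise SignatureError("signature probabilities must be non-negative")
        rs = P.sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-6):
            raise SignatureError("each signature row must sum to 1")
        self.probabilities = P
        self.names = [str(n) for n in self.names]

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        """Read a channels-x-signatures TSV (96 labelled rows, one column per signature)."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.loc[CHANNELS_96]
        return cls(df.to_numpy(float).T, list(df.columns))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.probabilities.T, index=CHANNELS_96,
                     columns=self.names).to_csv(path, sep="\t")


@dataclass
class Decomposition:
    exposures: np.ndarray
    names: list
    loglik_trace: list
    n_iterations: int

    def as_dict(self) -> dict:
        return {n: float(c) for n, c in zip(self.names, self.exposures)}


def em_decompose(spectrum, signatures: SignatureMatrix, tol: float = 1e-5,
                 max_iter: int = 10000, init: str = "uniform",
                 seed: int | None = None) -> Decomposition:
    """Maximum-likelihood signature exposures for one sample spectrum.

    ``spectrum`` is the vector of 96 channel counts.  The EM iteration
    computes per-channel responsibilities p_i proportional to c_i * m_i,j and
    re-normalizes their count-weighted sums; it stops when sum(|delta c|) <
    ``tol``.  The multinomial log-likelihood is non-decreasing across
    iterations.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.shape != (96,):
        raise SignatureError("spectrum must have 96 channels")
    if (x < 0).any() or x.sum() == 0:
        raise SignatureError("spectrum must be non-negative and not all zero")
    M = signatures.probabilities
    S = M.shape[0]
    dead = (M.sum(axis=0) == 0) & (x > 0)
    if dead.any():
        ch = CHANNELS_96[int(np.nonzero(dead)[0][0])]
        raise SignatureError(f"channel {ch} has observed mutations but zero "
                             "probability under every signature")

    if init == "uniform":
        c = np.full(S, 1.0 / S)
    elif init == "random":
        rng = np.random.default_rng(seed)
        c = rng.dirichlet(np.ones(S))
    else:
        raise SignatureError(f"unknown init {init!r}")

    total = x.sum()
    trace = []
    for it in range(1, max_iter + 1):
        mix = c @ M                                   # per-channel probability
        mix = np.maximum(mix, 1e-300)
        trace.append(float((x * np.log(mix)).sum()))
        resp = (c[:, None] * M) / mix[None, :]        # S x 96 responsibilities
        c_new = (resp * x[None, :]).sum(axis=1) / total
        if np.abs(c_new - c).sum() < tol:
            c = c_new
            break
        c = c_new
    mix = np.maximum(c @ M, 1e-300)
    trace.append(float((x * np.log(mix)).sum()))
    return Decomposition(exposures=c, names=list(signatures.names),
                         loglik_trace=trace, n_iterations=it)


def classify_hypermutator(exposures, names=None, burden: int = 0,
                          burden_threshold: int = 1000, dominance: float = 0.5,
                          labels: dict | None = None) -> str:
    """Label a sample by its dominant mutational process.

    Samples at or below ``burden_threshold`` coding substitutions return the
    ``not_hypermutator`` sentinel.  Exposures of signatures sharing a label
    (APOBEC = signatures 2 + 13) are summed before the dominance check; a
    label is assigned only when its merged exposure exceeds ``dominance``.
    """
    if isinstance(exposures, Decomposition):
        names = exposures.names
        exposures = exposures.exposures
    if names is None:
        raise SignatureError("signature names are required")
    if burden <= burden_threshold:
        return NOT_HYPERMUTATOR
    labels = DEFAULT_SIGNATURE_LABELS if labels is None else labels
    merged: dict[str, float] = {}
    for name, c in zip(names, exposures):
        label = labels.get(str(name))
        if label is not None:
            merged[label] = merged.get(label, 0.0) + float(c)
    if not merged:
        return "unclassified"
    best, weight = max(merged.items(), key=lambda kv: kv[1])
    return best if weight > dominance else "unclassified"
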