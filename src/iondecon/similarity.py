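"""Unit-mass spectral similarity measures.

Two scores are used in the package: the plain cosine on dense unit-mass
vectors (invariant-scan selection, dedup merging, simulation scoring) and the
NIST-style weighted cosine (library identity search), where each peak is
weighted by m/z^1 * intensity^0.5 before taking the cosine.
"""

from __future__ import annotations

import numpy as np

from .chromdata import Spectrum


def cosine(a: Spectrum, b: Spectrum) -> float:
    """Plain cosine similarity in [0, 1] on the shared unit-mass grid."""
    if not a or not b:
        return 0.0
    mzs = sorted(set(a.peaks) | set(b.peaks))
    va = np.array([a.get(m) for m in mzs])
    vb = np.array([b.get(m) for m in mzs])
    denom = np.linalg.norm(va) * np.linalg.norm(vb)
    if denom == 0:
        return 0.0
    return float(np.dot(va, vb) / denom)


def weighted_cosine(query: Spectrum, reference: Spectrum,
                    mz_power: float = 1.0, intensity_power: float = 0.5) -> float:
    """NIST-style identity score: cosine of (m/z^p * I^q)-weighted peak vectors."""
    if not query or not reference:
        return 0.0
    mzs = np.array(sorted(set(query.peaks) | set(reference.peaks)), dtype=float)
    w = mzs ** mz_power
    vq = w * np.array([query.get(int(m)) for m in mzs]) ** intensity_power
    vr = w * np.array([reference.get(int(m)) for m in mzs]) ** intensity_power
    denom = np.linalg.norm(vq) * np.linalg.norm(vr)
    if denom == 0:
        return 0.0
    return float(np.dot(vq, vr) / denom)


def pairwise_cosine_matrix(spectra: list[Spectrum]) -> np.ndarray:
    """Symmetric matrix of plain cosine similarities between spectra.

    Exposed as a diagnostic for the cross-scan comparison view of scan-to-scan
    variance: entry (i, j) compares scan i against scan j.
    """
    n = len(spectra)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = cosine(spectra[i], spectra[j])
    return out
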