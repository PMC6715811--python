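"""Synthetic FISH / Hi-C data generation for end-to-end testing.

Generates per-cell pairwise distances from a two-population mixture or from an
arbitrary subpopulation spectrum (inverse-CDF sampling on the incomplete-gamma
representation of the Redner–des Cloizeaux family, of which the chi / Gaussian
chain is the (0, 2) case), random loop-anchor sets for the simulator, and
Poisson pseudo-Hi-C counts with mean proportional to the true contact
probabilities so that relative contact frequencies are recoverable.

Optional Gaussian measurement noise on distances (truncated at zero) is
available but off by default: localization error is an extension, not part of
the mixture model itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .mixture import FISHDataset, MixtureModel
from .spectrum import SubpopulationSpectrum
from .theory import ContactTheoryParams, rdc_ppf, sigma_from_mean

__all__ = [
    "GeneratorConfig",
    "sample_distances",
    "sample_loopset",
    "sample_hic_counts",
]


@dataclass
class GeneratorConfig:
    """Recipe for one synthetic FISH dataset."""

    model: Union[MixtureModel, SubpopulationSpectrum]
    n_cells: int = 2000
    seed: int = 0
    noise: float = 0.0
    pair_id: str = "synthetic"

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be at least 1")
        if self.noise < 0:
            raise ValueError("noise must be nonnegative")


def _component_sample(rng, n, R, family, g, delta):
    """Inverse-CDF draw of n distances from one component with mean distance R."""
    u = rng.uniform(size=n)
    if family == "chi":
        # chi = RdC with (g, delta) = (0, 2); use scipy's chi ppf via the
        # generalized-gamma inverse for a single code path
        params = ContactTheoryParams(r_c=1.0, g=0.0, delta=2.0)
    else:
        params = ContactTheoryParams(r_c=1.0, g=g, delta=delta)
    return rdc_ppf(u, R, params)


def sample_distances(config: GeneratorConfig) -> FISHDataset:
    """Draw i.i.d. distances from a mixture model or a subpopulation spectrum.

    Each cell first picks its subpopulation (component weight for a mixture,
    grid weight for a spectrum), then draws a distance from that component's
    law by exact inverse-transform sampling.  Optional additive Gaussian
    noise is truncated at zero.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    model = config.model
    if isinstance(model, MixtureModel):
        means = np.array([model.R1, model.R2])
        weights = np.array([model.eta, 1.0 - model.eta])
        family, g, delta = model.family, model.g, model.delta
    else:
        means = model.R_grid
        weights = model.weights
        family, g, delta = "rdc", 1.0, 1.25
    comp = rng.choice(means.size, size=n, p=weights)
    r = np.empty(n)
    for c in np.unique(comp):
        sel = comp == c
        r[sel] = _component_sample(rng, int(sel.sum()), means[c], family, g, delta)
    if config.noise > 0:
        r = np.maximum(r + rng.normal(0.0, config.noise, size=n), 0.0)
    return FISHDataset(pair_id=config.pair_id, distances=r)


def sample_loopset(N: int, n_loops: int, min_span: int = 2, seed: int = 0):
    """Uniform random non-adjacent anchor pairs on a chain of N loci."""
    from .simulate import LoopSet

    if n_loops == 0:
        return LoopSet()
    if min_span < 2:
        raise ValueError("min_span must be >= 2 (adjacent loci are chain bonds)")
    rng = np.random.default_rng(seed)
    pairs = set()
    attempts = 0
    while len(pairs) < n_loops:
        p = int(rng.integers(0, N - min_span))
        q = int(rng.integers(p + min_span, N))
        pairs.add((p, q))
        attempts += 1
        if attempts > 1000 * n_loops:
            raise RuntimeError(
                f"could not place {n_loops} loops with min_span={min_span} on N={N}"
            )
    return LoopSet(sorted(pairs))


def sample_hic_counts(true_probs, depth: float, seed: int = 0) -> np.ndarray:
    """Poisson pseudo-Hi-C counts with mean ``depth * P_i`` per pair.

    Count ratios converge to contact-probability ratios as depth grows, so
    relative contact frequencies computed from these counts are unbiased
    estimates of the model's.
    """
    p = np.asarray(true_probs, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    return rng.poisson(depth * p)
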