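"""Forward model: templates + phasing + cross-talk + noise -> intensities.

The pure per-channel signal of a polony at cycle ``t`` is its brightness,
times the per-cycle decay, times the fraction of its strands currently
templating a position whose base matches the channel.  Observed signal mixes
pure channels through the spectral cross-talk matrix and adds Gaussian noise,
clipped at zero.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimConfig
from .phasing import phasing_state_matrix
from .templates import BASES, TemplateSet, encode_bases, generate_templates

__all__ = ["IntensityTensor", "render_intensities", "simulate_polonies"]

CHANNEL_ORDER = BASES  # A,C,G,T -> channels 0..3


@dataclass(frozen=True)
class IntensityTensor:
    """polony x cycle x channel signal values."""

    values: np.ndarray  # (n_polonies, cycles, 4)
    channel_order: str = CHANNEL_ORDER

    @property
    def n_polonies(self) -> int:
        return self.values.shape[0]

    @property
    def cycles(self) -> int:
        return self.values.shape[1]


def render_intensities(
    templates: TemplateSet, config: SimConfig
) -> tuple[IntensityTensor, np.ndarray]:
    """Render the observed intensity tensor and per-cycle ground truth.

    Returns ``(tensor, truth)`` where ``truth[n, t]`` is the channel index of
    the template base at position ``t`` (the error-free call).
    """
    n = len(templates)
    if n != config.n_polonies:
        raise ValueError(
            f"config.n_polonies={config.n_polonies} but {n} templates supplied"
        )
    T = config.read_length
    lengths = {len(s) for s in templates.sequences}
    if len(lengths) != 1:
        raise ValueError("all templates must have equal length")
    L = lengths.pop()
    if L < T:
        raise ValueError(f"templates of length {L} shorter than read_length {T}")

    tmpl = np.stack([encode_bases(s) for s in templates.sequences])  # (n, L)
    sd = phasing_state_matrix(config.p_lag, config.p_lead, T)
    J = min(L, sd.n_positions)
    onehot = (tmpl[:, :J, None] == np.arange(4)[None, None, :]).astype(float)

    rng = np.random.default_rng(config.seed)
    if config.brightness_cv > 0:
        sigma2 = np.log1p(config.brightness_cv**2)
        brightness = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)
    else:
        brightness = np.ones(n)
    decay = config.signal_decay_per_cycle ** np.arange(T)

    pure = np.einsum("tj,njc->ntc", sd.matrix[:, :J], onehot)
    pure *= brightness[:, None, None]
    pure *= decay[None, :, None]

    observed = np.einsum("dc,ntc->ntd", config.crosstalk, pure)
    if config.noise_sd > 0:
        observed = observed + rng.normal(0.0, config.noise_sd, size=observed.shape)
    np.clip(observed, 0.0, None, out=observed)

    truth = tmpl[:, :T].astype(np.uint8)
    return IntensityTensor(values=observed), truth


def simulate_polonies(
    config: SimConfig, template_pad: int = 0
) -> tuple[IntensityTensor, np.ndarray, TemplateSet]:
    """Convenience wrapper: draw random templates and render them.

    ``template_pad`` extends templates beyond the read length so prephased
    strands can template positions past the last cycle; with the default 0
    the truncated deconvolution used by the base caller is the exact inverse
    of this forward model.
    """
    templates = generate_templates(
        config.n_polonies, config.read_length + template_pad, seed=config.seed + 1
    )
    tensor, truth = render_intensities(templates, config)
    return tensor, truth, templates
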