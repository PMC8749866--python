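"""Reduced-scale reference configuration ("desk spec").

The full-scale defaults (232x232x32 crops, 110 epochs, widths 16-128) are
sized for GPU training on real MRI.  The desk spec is the package's
CPU-friendly study configuration for the synthetic phantoms: small blobs
with strongly blurred, heavily noised edges (so that edge learning is
genuinely hard), a narrow network, and a short Adam schedule with the
learning rate raised to suit it.  All reduced-scale experiments (tests, the
ablation CLI default, the acceptance script) share these values.
"""

from __future__ import annotations

from .networks import NetworkSpec
from .synthetic import PhantomSpec
from .training import TrainSpec

#: phantom geometry: 32x32x16 voxels at 0.625 mm, 3 lobes; blur sigma 2.0 and
#: noise sd 0.8 (80% of the fg/bg contrast) make the edge the hard part
DESK_PHANTOM = PhantomSpec(
    shape=(32, 32, 16),
    spacing=(0.625, 0.625, 0.625),
    n_lobes=3,
    edge_blur_sigma=2.0,
    noise_sd=0.8,
)

#: narrow 3-level network
DESK_NET = NetworkSpec(channel_widths=(4, 8, 16, 32), norm_groups=4)

#: short Adam schedule; lr0 raised for the ~140-step budget; stage 2 sees the
#: raw image alongside the bridged stage-1 outputs (automatic-context cascade)
DESK_TRAIN = TrainSpec(
    crop_size=(24, 24, 16),
    lr0=2e-3,
    max_epochs=20,
    stage2_include_image=True,
)

#: dataset sizing: 10 phantoms, 7 train / 3 validation; 3 replicate seeds
DESK_N_CASES = 10
DESK_N_TRAIN = 7
DESK_SEEDS = (0, 1, 2)
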