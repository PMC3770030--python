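"""End-to-end segmentation pipeline.

Stage order: MCDE denoise -> gradient magnitude -> sigmoid speed map ->
energy-decrement (if a standard line is given) -> fast marching ->
time-threshold initial region -> energy-tune of the edge map (line-based
or automatic) -> two-phase MDRLS evolution -> threshold -> morphological
cleanup.  Deterministic throughout: identical inputs and configuration
produce bit-identical masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import energy as en
from . import fast_marching as fm
from . import mdrls, postprocess, preprocess
from .config import PipelineConfig
from .features import edge_indicator, sigmoid_speed

__all__ = ["PipelineResult", "StageError", "STAGES", "run_pipeline"]

#: pipeline stages in execution order; a failure in stage i is reported
#: by the CLI with exit code 10 + i
STAGES = (
    "denoise",
    "gradient",
    "speed-map",
    "energy-decrement",
    "fast-marching",
    "initial-region",
    "energy-tune",
    "mdrls",
    "postprocess",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and index."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.index = STAGES.index(stage)
        super().__init__(f"stage '{stage}' failed: {cause}")


@dataclass(frozen=True)
class PipelineResult:
    """All intermediate and final products of a segmentation run."""

    denoised: np.ndarray
    gradient: np.ndarray
    speed: np.ndarray
    fm_energy: np.ndarray  # speed after energy-decrement (== speed without a line)
    time_map: np.ndarray
    initial_region: np.ndarray
    edge_map: np.ndarray
    tuned_energy: np.ndarray  # Et driving the level set (== edge_map if tune disabled)
    phi: np.ndarray
    mask_raw: np.ndarray
    mask: np.ndarray


def run_pipeline(
    image: np.ndarray,
    seeds: fm.SeedSet,
    line: en.StandardLine | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Segment one 2-D slice from seed points (and an optional standard line).

    When ``line`` is None the pipeline runs the automatic variants: the
    fast-marching front uses the raw speed map, and the level-set edge map
    is tuned by the distance-threshold rule instead of the line rule.
    """
    cfg = config or PipelineConfig()
    image = np.asarray(image, dtype=np.float64)
    seeds.validate(image.shape)

    stage = STAGES[0]
    try:
        den = preprocess.mcde_denoise(
            image,
            conductance=cfg.preprocess.conductance,
            time_step=cfg.preprocess.time_step,
            n_iters=cfg.preprocess.n_iters,
        )
        stage = "gradient"
        gm = preprocess.gradient_magnitude(den, sigma=cfg.preprocess.sigma)
        stage = "speed-map"
        speed = sigmoid_speed(
            gm,
            alpha=cfg.sigmoid.alpha,
            beta=cfg.sigmoid.beta,
            out_min=cfg.sigmoid.out_min,
            out_max=cfg.sigmoid.out_max,
        )

        stage = "energy-decrement"
        d_line = None
        if line is not None:
            d_line = en.distance_to_line(line, image.shape)
            fm_energy = en.energy_decrement(speed, d_line, t_d=cfg.energy.t_d)
        else:
            fm_energy = speed

        stage = "fast-marching"
        time_map = fm.solve_eikonal(fm_energy, seeds)
        stage = "initial-region"
        r0 = fm.extract_initial_region(time_map, t_star=cfg.fm.t_star)

        stage = "energy-tune"
        g = edge_indicator(gm)
        if cfg.energy.enable_tune:
            e_src = en.source_energy(
                r0, g, sigma=cfg.energy.sigma, boundary_only=cfg.energy.boundary_only
            )
            d_src = en.distance_to_mask(r0)
            if line is not None:
                et = en.energy_tune_line(
                    g, e_src, r0, d_line, d_src,
                    tune_alpha=cfg.energy.tune_alpha, tune_beta=cfg.energy.tune_beta,
                )
            else:
                et = en.energy_tune_auto(
                    g, e_src, r0, d_src, d_t=cfg.energy.d_t,
                    tune_alpha=cfg.energy.tune_alpha, tune_beta=cfg.energy.tune_beta,
                )
        else:
            et = g

        stage = "mdrls"
        phi0 = mdrls.init_lsf(r0, c=cfg.mdrls.c)
        phi = mdrls.segment_two_phase(phi0, et, cfg.mdrls)

        stage = "postprocess"
        mask_raw = postprocess.lsf_to_mask(phi)
        mask = postprocess.morphological_cleanup(
            mask_raw, radius=cfg.post.radius, min_component=cfg.post.min_component
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    return PipelineResult(
        denoised=den,
        gradient=gm,
        speed=speed,
        fm_energy=fm_energy,
        time_map=time_map,
        initial_region=r0,
        edge_map=g,
        tuned_energy=et,
        phi=phi,
        mask_raw=mask_raw,
        mask=mask,
    )
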