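"""Named parameter presets for the segmentation pipeline.

Each preset reproduces a published parameter set for a particular trial field
and imagery type (Canny/PC sigma, hysteresis threshold where one was needed,
and the minimum plot area in m²). Values the source never stated fall through
to library defaults; the run log flags them as defaulted.

* ``cae_tatws_cn``    — senescent oats, orthomosaic, Canny sigma 4, min area 3.5 m²
* ``cae_tatws_pc``    — same field, phase congruency (sigma 2, noise multiplier 1)
* ``cae_gwyn8``       — flowering oats, Canny sigma 6, min area 2.4 m²
* ``cae_gwyn7_dual``  — emergence-stage oats, per-axis Canny (sigma 4 with
                        threshold 6 on the major axis, sigma 40 on the minor),
                        min area 8 m²
* ``cae_rasus4_dsm``  — emergence-stage mixed cereals on a DSM, Canny sigma 10,
                        min area 10 m²

The PC threshold convention of the source material is ambiguous (phase
congruency is unitless in [0, 1]); the published value of 1 is interpreted as
the noise-threshold multiplier ``k``.
"""

from __future__ import annotations

from .edges import CannyParams, PCParams
from .plots import PipelineConfig

PRESETS: dict[str, dict] = {
    "cae_tatws_cn": {
        "edge_algorithm": "CN",
        "canny": {"sigma": 4.0},
        "min_area_m2": 3.5,
    },
    "cae_tatws_pc": {
        "edge_algorithm": "PC",
        "pc": {"sigma": 2.0, "k": 1.0},
        "min_area_m2": 3.5,
    },
    "cae_gwyn8": {
        "edge_algorithm": "CN",
        "canny": {"sigma": 6.0},
        "min_area_m2": 2.4,
    },
    "cae_gwyn7_dual": {
        "edge_algorithm": "CN",
        "dual_axis": True,
        "canny": {"sigma": 4.0, "upper": 6.0},
        "canny_minor": {"sigma": 40.0},
        "min_area_m2": 8.0,
    },
    "cae_rasus4_dsm": {
        "edge_algorithm": "CN",
        "canny": {"sigma": 10.0},
        "min_area_m2": 10.0,
    },
}


def preset_names() -> list[str]:
    return sorted(PRESETS)


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a plain (YAML/JSON-style) mapping."""
    from .plots import HoughConfig
    from .refine import RefineParams

    data = dict(data)
    kwargs: dict = {}
    for key in (
        "edge_algorithm",
        "dual_axis",
        "min_area_m2",
        "max_area_m2",
        "refine",
        "line_width_px",
        "grayscale",
    ):
        if key in data:
            kwargs[key] = data[key]
    if "canny" in data:
        kwargs["canny"] = CannyParams(**data["canny"])
    if "canny_minor" in data and data["canny_minor"] is not None:
        kwargs["canny_minor"] = CannyParams(**data["canny_minor"])
    if "pc" in data:
        kwargs["pc"] = PCParams(**data["pc"])
    if "pc_minor" in data and data["pc_minor"] is not None:
        kwargs["pc_minor"] = PCParams(**data["pc_minor"])
    if "hough" in data:
        kwargs["hough"] = HoughConfig(**data["hough"])
    if "refine_params" in data and data["refine_params"] is not None:
        kwargs["refine_params"] = RefineParams(**data["refine_params"])
    return PipelineConfig(**kwargs)


def config_to_dict(config: PipelineConfig) -> dict:
    """Serialize a config to a plain mapping; inverse of :func:`config_from_dict`."""
    out: dict = {
        "edge_algorithm": config.edge_algorithm,
        "canny": {k: v for k, v in config.canny.__dict__.items() if v is not None},
        "pc": dict(config.pc.__dict__),
        "dual_axis": config.dual_axis,
        "min_area_m2": config.min_area_m2,
        "max_area_m2": config.max_area_m2,
        "hough": dict(config.hough.__dict__),
        "refine": config.refine,
        "line_width_px": config.line_width_px,
        "grayscale": config.grayscale,
    }
    if config.canny_minor is not None:
        out["canny_minor"] = {k: v for k, v in config.canny_minor.__dict__.items() if v is not None}
    if config.pc_minor is not None:
        out["pc_minor"] = dict(config.pc_minor.__dict__)
    if config.refine_params is not None:
        out["refine_params"] = dict(config.refine_params.__dict__)
    return out


def preset_config(name: str) -> PipelineConfig:
    try:
        return config_from_dict(PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(preset_names())}")
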