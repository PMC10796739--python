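"""Pipeline configuration: one home for every tunable constant.

Defaults follow the analysis protocol: 0.1-12 Hz 4th-order Butterworth
band-pass, 25 Hz working rate, 3 s windows with 70% overlap, the 1/3 GDM
window-labelling rule, a 20 stroke + 10 control cohort, and the gbt
detector backend.
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass, field

import yaml

from .preprocess import FilterSpec


@dataclass
class PipelineConfig:
    # cohort simulation
    n_stroke: int = 20
    n_control: int = 10
    session_s: float = 120.0
    fs_raw: float = 100.0
    # preprocessing
    filter: FilterSpec = field(default_factory=FilterSpec)
    fs_target: float = 25.0
    # windowing
    window_s: float = 3.0
    overlap: float = 0.7
    gdm_window_fraction: float = 1.0 / 3.0
    # detection / evaluation
    backend: str = "gbt"
    seed: int = 0
    # downstream
    vote_rule: str = "majority"

    def to_yaml(self) -> str:
        d = asdict(self)
        d["filter"] = asdict(self.filter)
        buf = io.StringIO()
        yaml.safe_dump(d, buf, sort_keys=False)
        return buf.getvalue()

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        if "filter" in d:
            d["filter"] = FilterSpec(**d["filter"])
        return cls(**d)


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Return a list of problems; an empty list means the config is valid."""
    problems: list[str] = []
    if cfg.n_stroke < 0 or cfg.n_control < 0:
        problems.append("subject counts must be non-negative")
    if cfg.fs_raw < 50:
        problems.append("fs_raw must be at least 50 Hz")
    if cfg.fs_raw % cfg.fs_target != 0:
        problems.append("fs_raw must be an integer multiple of fs_target")
    if not 0 < cfg.filter.low_hz < cfg.filter.high_hz:
        problems.append("filter band must satisfy 0 < low_hz < high_hz")
    if cfg.filter.high_hz >= cfg.fs_target / 2:
        problems.append(
            f"filter high edge {cfg.filter.high_hz} Hz violates the "
            f"{cfg.fs_target / 2} Hz Nyquist of the target rate"
        )
    if not 0 <= cfg.overlap < 1:
        problems.append("overlap must lie in [0, 1)")
    elif int(round(cfg.window_s * cfg.fs_target) * (1 - cfg.overlap)) < 1:
        problems.append("overlap too high: zero window hop")
    if cfg.window_s * cfg.fs_target < 2:
        problems.append("window too short")
    if not 0 < cfg.gdm_window_fraction <= 1:
        problems.append("gdm_window_fraction must lie in (0, 1]")
    if cfg.backend != "gbt":
        problems.append(f"unsupported backend: {cfg.backend!r}")
    if cfg.vote_rule not in ("majority", "any"):
        problems.append(f"unknown vote rule: {cfg.vote_rule!r}")
    if cfg.session_s < cfg.window_s:
        problems.append("session shorter than one window")
    return problems
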