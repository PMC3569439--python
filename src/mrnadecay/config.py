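"""Run configuration shared by the fitting pipeline and the CLI."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass


@dataclass
class RunConfig:
    """Tunable thresholds and optimizer settings for the pipeline.

    ``rss_improvement_threshold`` is the nested-model selection rule (a
    non-exponential fit must lower the RSS by this fraction to be kept);
    ``rss_accuracy_threshold`` is the "fitted accurately" RSS cut used in
    summaries; ``bona_fide_tol`` is the near-pass tolerance of the
    convexity screen.
    """

    bona_fide_tol: float = 0.05
    rss_improvement_threshold: float = 0.10
    rss_accuracy_threshold: float = 0.01
    n_states: int = 5
    rate_lower_bound: float = 1e-6
    rate_upper_bound: float = 10.0
    n_starts: int = 8
    seed: int = 0

    def __post_init__(self):
        for name in ("rss_improvement_threshold", "rss_accuracy_threshold", "bona_fide_tol"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        if not 0 < self.rate_lower_bound < self.rate_upper_bound:
            raise ValueError("rate bounds must satisfy 0 < lower < upper")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))
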