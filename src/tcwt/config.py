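"""Analysis configuration shared by the evaluation protocols and the pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable parameters of a run.

    Attributes
    ----------
    s_c:
        Cutoff scale in seconds (cutoff frequency 1/s_c; frequencies up to
        2/s_c are retained).
    grid_rate:
        Scale-invariant log-grid sampling rate R in points per scale.
    t_in, t_out:
        Fade-in duration and fade-out start time (s) of the time-window
        envelope; ``t_out=None`` disables the fade-out.
    pca_criterion:
        Proportion of explained variance P_v in (0, 100] or ``"average"``.
    c_individual, c_group:
        Outlier threshold coefficients for individual and pooled-group
        analyses.
    dataset_limit:
        Fraction of flagged trials above which a whole dataset is flagged.
    alpha_sd:
        Overall level of the step-down component-selection test.
    priors:
        (p_A, p_B) a-priori class probabilities; ``None`` means equal.
    holdout_stride:
        Classify every ``holdout_stride``-th retained trial in the individual
        hold-out loop (1 = full leave-one-out).
    block_size:
        Trial block size of the CWT transform (memory knob only).
    """

    s_c: float = 0.04
    grid_rate: int = 15
    t_in: float = 0.02
    t_out: float | None = 0.2
    pca_criterion: object = 99.0
    group_pca_criterion: object = "average"
    c_individual: float = 2.7
    c_group: float = 2.5
    dataset_limit: float = 0.5
    alpha_sd: float = 0.3
    priors: tuple[float, float] | None = None
    holdout_stride: int = 1
    block_size: int = 64
    max_iter: int = 100
    condition_a: str | None = None
    condition_b: str | None = None

    def validate(self) -> "RunConfig":
        if self.s_c <= 0:
            raise ValueError("s_c must be positive")
        if self.grid_rate < 1:
            raise ValueError("grid_rate must be >= 1")
        if not (0 < self.alpha_sd <= 1):
            raise ValueError("alpha_sd must lie in (0, 1]")
        if self.c_individual <= 0 or self.c_group <= 0:
            raise ValueError("outlier coefficients must be positive")
        if not (0 < self.dataset_limit <= 1):
            raise ValueError("dataset_limit must lie in (0, 1]")
        if self.priors is not None:
            pa, pb = self.priors
            if not (0 < pa < 1 and 0 < pb < 1 and abs(pa + pb - 1) < 1e-9):
                raise ValueError("priors must lie in (0,1) and sum to 1")
        if self.holdout_stride < 1 or self.block_size < 1:
            raise ValueError("strides and block sizes must be >= 1")
        if isinstance(self.pca_criterion, str):
            if self.pca_criterion != "average":
                raise ValueError("pca_criterion must be a percentage or 'average'")
        elif not (0 < float(self.pca_criterion) <= 100):
            raise ValueError("pca_criterion percentage must lie in (0, 100]")
        return self

    def digest(self, *extra: str) -> str:
        """Stable hash of the configuration (keys all pipeline caches)."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        h = hashlib.sha256(payload.encode())
        for item in extra:
            h.update(item.encode())
        return h.hexdigest()[:16]
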