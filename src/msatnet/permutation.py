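"""Shared result type for permutation / Monte-Carlo tests."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TestResult", "mc_pvalue"]


def mc_pvalue(n_exceed: int, n_reps: int) -> float:
    """Permutation p-value with +1 smoothing: ``(exceed + 1) / (reps + 1)``.

    The convention guarantees p > 0 and makes the p-value exact under the
    randomisation null (the observed statistic counts as one realisation).
    """
    return (n_exceed + 1) / (n_reps + 1)


@dataclass
class TestResult:
    """Outcome of a randomisation test."""

    statistic: float
    p_value: float | None
    n_permutations: int
    seed: int | None
    method: str
    status: str = "ok"

    @property
    def testable(self) -> bool:
        return self.status == "ok"

    def __repr__(self) -> str:  # compact, log-friendly
        p = "NA" if self.p_value is None else f"{self.p_value:.4g}"
        return (
            f"TestResult({self.method}: stat={self.statistic:.4g}, p={p}, "
            f"n={self.n_permutations}, status={self.status})"
        )
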