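"""Observer reliability statistics: variation and intraclass correlation.

The validation design repeats the full landmark-to-report analysis per
patient across sessions (observer 1 twice, four weeks apart, plus observer
2).  Reliability is summarised per report component by

* *observer variation* — the mean over patients of the absolute
  between-session difference, with a seeded percentile-bootstrap 95% CI, and
* *ICC(2,1)* — the two-way random-effects, absolute-agreement,
  single-measures intraclass correlation, with its F-distribution CI.

Missing cells are refused: reliability statistics must not impute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SESSION_LABELS",
    "MeasurementGrid",
    "ReliabilityResult",
    "observer_variation",
    "icc",
]

#: Conventional session labels of the three-session validation design.
SESSION_LABELS = ("observer1_t1", "observer1_t2", "observer2")


@dataclass(frozen=True)
class ReliabilityResult:
    """One reliability statistic for one report component.

    ``value`` is in mm or degrees for variation statistics and unitless in
    [-1, 1] for ICC; ``ci_low``/``ci_high`` bound the 95% interval.
    """

    component: str
    statistic: str
    value: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if self.statistic == "icc" and self.value > 1 + 1e-12:
            raise ValueError(f"ICC {self.value} exceeds 1")
        if self.statistic == "variation" and not (
                self.ci_low - 1e-12 <= self.value <= self.ci_high + 1e-12):
            raise ValueError(
                f"CI [{self.ci_low}, {self.ci_high}] does not bracket "
                f"{self.value}")


class MeasurementGrid:
    """Values indexed by (patient, session, component).

    Wraps a long-format DataFrame with columns ``patient``, ``session``,
    ``component``, ``value``.  Requires at least two patients and two
    sessions; duplicate cells are an error.
    """

    def __init__(self, data: pd.DataFrame):
        required = {"patient", "session", "component", "value"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"grid lacks columns {sorted(missing)}")
        df = data.loc[:, ["patient", "session", "component", "value"]].copy()
        df["value"] = df["value"].astype(float)
        if df.duplicated(["patient", "session", "component"]).any():
            raise ValueError("duplicate (patient, session, component) cells")
        if df["patient"].nunique() < 2:
            raise ValueError("grid needs at least 2 patients")
        if df["session"].nunique() < 2:
            raise ValueError("grid needs at least 2 sessions")
        self.data = df

    @property
    def patients(self) -> list:
        return sorted(self.data["patient"].unique().tolist())

    @property
    def sessions(self) -> list:
        return sorted(self.data["session"].unique().tolist())

    @property
    def components(self) -> list:
        return sorted(self.data["component"].unique().tolist())

    def matrix(self, component: str, sessions: list | None = None) -> np.ndarray:
        """Patients x sessions value matrix for one component; raises on any
        missing cell."""
        sessions = list(sessions or self.sessions)
        sub = self.data[self.data["component"] == component]
        if sub.empty:
            raise KeyError(f"component {component!r} not in grid")
        pivot = sub.pivot(index="patient", columns="session", values="value")
        try:
            pivot = pivot.loc[:, sessions]
        except KeyError as exc:
            raise KeyError(f"session missing for {component!r}: {exc}") from exc
        if pivot.isna().any().any():
            raise ValueError(
                f"missing cells for component {component!r}; reliability "
                "statistics refuse incomplete grids")
        return pivot.sort_index().to_numpy(dtype=float)

    @classmethod
    def from_records(cls, records) -> "MeasurementGrid":
        return cls(pd.DataFrame.from_records(
            records, columns=["patient", "session", "component", "value"]))


def observer_variation(grid: MeasurementGrid, session_a: str, session_b: str,
                       n_boot: int = 10_000, seed: int = 0,
                       ) -> dict[str, ReliabilityResult]:
    """Mean absolute between-session difference per component.

    The 95% CI is a percentile bootstrap over patients (``n_boot`` resamples,
    seeded, deterministic).  Symmetric in the two sessions and non-negative
    by construction.
    """
    results = {}
    rng = np.random.default_rng(seed)
    for comp in grid.components:
        m = grid.matrix(comp, [session_a, session_b])
        if m.shape[0] < 2:
            raise ValueError("observer variation needs at least 2 patients")
        diffs = np.abs(m[:, 0] - m[:, 1])
        value = float(diffs.mean())
        idx = rng.integers(0, len(diffs), size=(n_boot, len(diffs)))
        boot = diffs[idx].mean(axis=1)
        lo, hi = np.percentile(boot, [2.5, 97.5])
        results[comp] = ReliabilityResult(comp, "variation", value,
                                          float(lo), float(hi))
    return results


def icc(grid: MeasurementGrid,
        sessions: list | None = None) -> dict[str, ReliabilityResult]:
    """ICC(2,1) per component: two-way random effects, absolute agreement,
    single measures, with the F-distribution 95% CI.

    Raises when the between-patient variance is (near-)zero — the ICC is
    undefined there, not silently 0.
    """
    import pingouin as pg

    sessions = list(sessions or grid.sessions)
    if len(sessions) < 2:
        raise ValueError("ICC needs at least 2 sessions")
    results = {}
    for comp in grid.components:
        m = grid.matrix(comp, sessions)
        n_pat, n_ses = m.shape
        if n_pat < 3:
            raise ValueError("ICC needs at least 3 patients")
        if np.var(m.mean(axis=1)) < 1e-15 * max(1.0, float(np.var(m))):
            raise ValueError(
                f"component {comp!r}: between-patient variance is zero; "
                "ICC is undefined")
        long = pd.DataFrame({
            "patient": np.repeat(np.arange(n_pat), n_ses),
            "session": np.tile(np.arange(n_ses), n_pat),
            "value": m.ravel(),
        })
        table = pg.intraclass_corr(data=long, targets="patient",
                                   raters="session", ratings="value")
        row = table.set_index("Type").loc["ICC(A,1)"]
        lo, hi = row["CI95"]
        results[comp] = ReliabilityResult(comp, "icc", float(row["ICC"]),
                                          float(lo), float(hi))
    return results
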