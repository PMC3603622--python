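"""Model/Results facade over the coupled simulator.

Typical use::

    from coroflow import CoronaryCirculationModel

    model = CoronaryCirculationModel.from_scenario("healthy")
    res = model.simulate()
    print(res.summary())
    res.ffr()            # for stenosis scenarios
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .network import ScenarioConfig, apply_scenario
from .solver import SimulationResult, run_to_periodic

MMHG = 133.322


class CoronaryCirculationResults:
    """Results wrapper: summary table, metrics and plotting for one run."""

    def __init__(self, result: SimulationResult):
        self.raw = result
        self._summary = _metrics.summarize(result)

    def __getattr__(self, item: str) -> Any:
        return getattr(self.raw, item)

    def summary(self) -> pd.Series:
        """Headline hemodynamic numbers of the final converged cycle."""
        return pd.Series(self._summary.as_dict(), name=self.raw.config.name)

    def ffr(self, segment: str = "LAD_c") -> float:
        return _metrics.ffr_across_stenosis(self.raw, segment)

    def flow_ratio(self, segment: str, pos: float = 0.0) -> float:
        return _metrics.dias_sys_flow_ratio(self.raw.flow(segment, pos),
                                            self.raw.systole)

    def transvalvular_gradient_mmhg(self) -> float:
        return _metrics.transvalvular_gradient(self.raw) / MMHG

    def to_dataframe(self, channels: dict[str, tuple[str, float]] | None = None
                     ) -> pd.DataFrame:
        """Selected channels as a tidy frame; default: heart + aortic root."""
        data = {
            "t": self.raw.t,
            "p_lv": self.raw.p_lv, "p_im": self.raw.p_im,
            "V_lv": self.raw.V_lv,
            "Q_mv": self.raw.Q_mv, "Q_av": self.raw.Q_av,
            "p_ao": self.raw.P[0], "systole": self.raw.systole,
        }
        for name, (seg, pos) in (channels or {}).items():
            data[name] = self.raw.flow(seg, pos)
        return pd.DataFrame(data)

    def plot_summary(self, path: str | None = None):
        """Four-panel overview: PV loop, pressures, valve flows, coronary flows."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        r = self.raw
        fig, ax = plt.subplots(2, 2, figsize=(9, 7))
        ax[0, 0].plot(r.V_lv * 1e6, r.p_lv / MMHG)
        ax[0, 0].set(xlabel="V_lv [mL]", ylabel="p_lv [mmHg]", title="PV loop")
        t = r.t - r.t[0]
        ax[0, 1].plot(t, r.p_lv / MMHG, "--", label="p_lv")
        ax[0, 1].plot(t, r.P[0] / MMHG, label="p_ao")
        ax[0, 1].set(xlabel="t [s]", ylabel="p [mmHg]"); ax[0, 1].legend()
        ax[1, 0].plot(t, r.Q_av * 1e6, label="Q_av")
        ax[1, 0].plot(t, r.Q_mv * 1e6, "--", label="Q_mv")
        ax[1, 0].set(xlabel="t [s]", ylabel="Q [mL/s]"); ax[1, 0].legend()
        try:
            ax[1, 1].plot(t, r.flow("LMCA") * 1e6, label="LMCA")
            ax[1, 1].plot(t, r.flow("RCA_b") * 1e6, "--", label="RCA")
            ax[1, 1].legend()
        except KeyError:
            pass
        ax[1, 1].set(xlabel="t [s]", ylabel="Q [mL/s]")
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


@dataclass
class CoronaryCirculationModel:
    """Coupled heart + 1D arterial network + microvascular terminals.

    Build from a named scenario (``from_scenario``) or a fully specified
    :class:`~coroflow.network.ScenarioConfig`; ``simulate`` integrates to
    periodic steady state and returns a results object.
    """

    config: ScenarioConfig
    dt: float = 5e-4
    max_cycles: int = 30
    tol: float = 1e-3

    @classmethod
    def from_scenario(cls, name: str, coronary_wall: str = "langewouters",
                      **kwargs) -> "CoronaryCirculationModel":
        return cls(config=apply_scenario(name, coronary_wall=coronary_wall), **kwargs)

    def simulate(self, **overrides) -> CoronaryCirculationResults:
        dt = overrides.pop("dt", self.dt)
        max_cycles = overrides.pop("max_cycles", self.max_cycles)
        tol = overrides.pop("tol", self.tol)
        if overrides:
            raise TypeError(f"unknown simulate() options {sorted(overrides)}")
        raw = run_to_periodic(self.config, dt=dt, max_cycles=max_cycles, tol=tol)
        return CoronaryCirculationResults(raw)

    # statsmodels-style alias
    fit = simulate
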