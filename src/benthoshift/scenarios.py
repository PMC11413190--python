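"""Scenario bookkeeping: the current decade plus future decade x SSP combos."""

from __future__ import annotations

from dataclasses import dataclass

DECADES = ("current", "2030", "2050")
SSPS = (2.6, 4.5, 7.0, 8.5)


@dataclass(frozen=True)
class ScenarioSpec:
    """One scenario: decade in {current, 2030, 2050}; ssp is None exactly
    when decade is current."""

    decade: str = "current"
    ssp: float | None = None

    def __post_init__(self) -> None:
        if self.decade not in DECADES:
            raise ValueError(f"decade must be one of {DECADES}")
        if (self.ssp is None) != (self.decade == "current"):
            raise ValueError("ssp must be None iff decade is 'current'")
        if self.ssp is not None and self.ssp not in SSPS:
            raise ValueError(f"ssp must be one of {SSPS}")

    @property
    def is_current(self) -> bool:
        return self.decade == "current"

    @property
    def name(self) -> str:
        return "current" if self.is_current else f"{self.decade}_{self.ssp}"


CURRENT = ScenarioSpec()


def future_scenarios(
    decades: tuple[str, ...] = ("2030", "2050"), ssps: tuple[float, ...] = SSPS
) -> list[ScenarioSpec]:
    """All future decade x SSP combinations, deterministic order."""
    return [ScenarioSpec(d, s) for d in decades for s in ssps]


def all_scenarios(
    decades: tuple[str, ...] = ("2030", "2050"), ssps: tuple[float, ...] = SSPS
) -> list[ScenarioSpec]:
    return [CURRENT] + future_scenarios(decades, ssps)
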