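"""Probe panel: which capture probe sits at which post sub-position.

Each well carries the same panel.  A post is one of three roles:

* ``endogenous`` — probes a miRNA expected in the sample (miR-167a, ...);
* ``internal_control`` — a biotinylated probe that labels regardless of
  sample, validating the ligation/labelling chemistry per well;
* ``negative_control`` — probes a miRNA absent from the organism
  (cel-miR-54 for *Arabidopsis*); its per-well signal is subtracted from
  every other probe's signal.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PanelEntry", "PanelDefinition", "ROLES"]

ROLES = ("endogenous", "internal_control", "negative_control")


@dataclass(frozen=True)
class PanelEntry:
    post_index: int
    target_name: str
    role: str


@dataclass(frozen=True)
class PanelDefinition:
    """Mapping of post sub-positions to probe targets and roles."""

    entries: tuple[PanelEntry, ...]

    def __post_init__(self) -> None:
        entries = tuple(
            e if isinstance(e, PanelEntry) else PanelEntry(*e) for e in self.entries
        )
        object.__setattr__(self, "entries", entries)
        indices = [e.post_index for e in entries]
        if sorted(indices) != list(range(len(entries))):
            raise ValueError(
                f"post_index values must be unique and cover 0..{len(entries) - 1}, "
                f"got {sorted(indices)}"
            )
        for e in entries:
            if e.role not in ROLES:
                raise ValueError(f"unknown role {e.role!r} for {e.target_name!r}")
        n_neg = sum(e.role == "negative_control" for e in entries)
        if n_neg != 1:
            raise ValueError(f"exactly one negative_control required, got {n_neg}")
        if sum(e.role == "internal_control" for e in entries) > 1:
            raise ValueError("at most one internal_control allowed")
        if not any(e.role == "endogenous" for e in entries):
            raise ValueError("at least one endogenous entry required")
        names = [e.target_name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("target names must be unique")

    @property
    def posts_per_well(self) -> int:
        return len(self.entries)

    @property
    def targets(self) -> list[str]:
        return [e.target_name for e in sorted(self.entries, key=lambda e: e.post_index)]

    @property
    def endogenous_targets(self) -> list[str]:
        return [
            e.target_name
            for e in sorted(self.entries, key=lambda e: e.post_index)
            if e.role == "endogenous"
        ]

    @property
    def negative_control(self) -> PanelEntry:
        return next(e for e in self.entries if e.role == "negative_control")

    @property
    def internal_control(self) -> PanelEntry | None:
        return next((e for e in self.entries if e.role == "internal_control"), None)

    def target_of(self, post_index: int) -> PanelEntry:
        for e in self.entries:
            if e.post_index == post_index:
                return e
        raise IndexError(f"no panel entry at post_index {post_index}")


def default_panel() -> PanelDefinition:
    """The reference 5-plex plant panel: three endogenous miRNAs plus controls."""
    return PanelDefinition(
        entries=(
            PanelEntry(0, "miR-167a", "endogenous"),
            PanelEntry(1, "miR-159a", "endogenous"),
            PanelEntry(2, "miR-396b", "endogenous"),
            PanelEntry(3, "internal-control", "internal_control"),
            PanelEntry(4, "cel-miR-54", "negative_control"),
        )
    )
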