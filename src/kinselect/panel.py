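"""Kinase-panel residual-activity tables: reading, validation, collapsing, writing.

A *panel* is the standard single-concentration selectivity readout: each
kinase in a profiling panel is assayed with and without inhibitor at one
fixed inhibitor concentration, and the result is reported as residual
activity in percent of the uninhibited control (100 % = untouched; values
above 100 % indicate apparent activation and are retained verbatim at this
layer).

A panel may list the profiled target more than once (e.g. the CK2
holoenzyme α₂β₂ tetramer and the isolated catalytic α subunit as separate
rows).  Panel-wide statistics count each biological target once, so
:func:`collapse_panel` merges rows sharing a ``group_key`` down to a single
representative before any selectivity statistic is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "PanelEntry",
    "KinasePanel",
    "PanelValidationError",
    "read_panel",
    "collapse_panel",
    "write_panel",
    "load_quinalizarin_panel",
    "load_ck2_forms",
    "DEFAULT_REPRESENTATIVES",
]

logger = logging.getLogger(__name__)

#: Default column names of the panel CSV dialect.
DEFAULT_DIALECT: Mapping[str, str] = {
    "kinase": "kinase",
    "activity_percent": "activity_percent",
    "group_key": "group_key",
    "is_reference_target": "is_reference_target",
}

#: Default representative per duplicated group: the CK2 holoenzyme row
#: stands for CK2, matching the convention under which the panel counts
#: each kinase once.
DEFAULT_REPRESENTATIVES: Mapping[str, str] = {"CK2": "CK2α2β2"}

COLLAPSE_POLICIES = ("keep-first", "keep-min-activity", "keep-named-representative")


class PanelValidationError(ValueError):
    """A panel table violates the format or value contract."""


@dataclass(frozen=True)
class PanelEntry:
    """One kinase row of a selectivity panel.

    Parameters
    ----------
    kinase_name
        Label of the kinase (whitespace-trimmed, case preserved).
    activity_percent
        Residual activity in percent of the uninhibited control; must be
        >= 0 and may exceed 100.
    group_key
        Canonical identifier used to merge redundant rows of the same
        biological target; defaults to ``kinase_name``.
    is_reference_target
        Marks rows belonging to the profiled target itself.
    """

    kinase_name: str
    activity_percent: float
    group_key: str = ""
    is_reference_target: bool = False

    def __post_init__(self) -> None:
        name = self.kinase_name.strip()
        if not name:
            raise PanelValidationError("kinase_name must be nonempty")
        object.__setattr__(self, "kinase_name", name)
        if not (self.activity_percent >= 0):  # also rejects NaN
            raise PanelValidationError(
                f"activity_percent must be >= 0, got {self.activity_percent!r} "
                f"for kinase {name!r}"
            )
        object.__setattr__(
            self, "group_key", (self.group_key or name).strip() or name
        )


@dataclass(frozen=True)
class KinasePanel:
    """An ordered collection of :class:`PanelEntry` at one inhibitor concentration."""

    inhibitor_name: str
    inhibitor_conc_uM: float
    entries: tuple[PanelEntry, ...]
    dropped: tuple[PanelEntry, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.inhibitor_conc_uM > 0):
            raise PanelValidationError("inhibitor_conc_uM must be > 0")
        names = [e.kinase_name for e in self.entries]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise PanelValidationError(f"duplicate kinase names in panel: {dup}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def is_collapsed(self) -> bool:
        keys = [e.group_key for e in self.entries]
        return len(set(keys)) == len(keys)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kinase": [e.kinase_name for e in self.entries],
                "activity_percent": [e.activity_percent for e in self.entries],
                "group_key": [e.group_key for e in self.entries],
                "is_reference_target": [e.is_reference_target for e in self.entries],
            }
        )


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return False
    text = str(value).strip().lower()
    if text in {"", "0", "false", "no", "nan"}:
        return False
    if text in {"1", "true", "yes"}:
        return True
    raise PanelValidationError(f"unrecognized boolean flag {value!r}")


def read_panel(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    *,
    inhibitor_name: str = "",
    inhibitor_conc_uM: float = 1.0,
) -> KinasePanel:
    """Read a panel CSV into a :class:`KinasePanel`, preserving row order.

    The CSV must carry a header; required columns are ``kinase`` and
    ``activity_percent`` (renameable via *dialect*, a mapping from the
    canonical names to the file's column names).  ``group_key`` and
    ``is_reference_target`` are optional.  Rows with missing or
    non-numeric activity are rejected with a row-numbered error, never
    dropped silently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, dtype={cols["kinase"]: str})
    for canonical in ("kinase", "activity_percent"):
        if cols[canonical] not in df.columns:
            raise PanelValidationError(
                f"missing required column {cols[canonical]!r} in {path}"
            )
    if len(df.columns) != len(set(df.columns)):
        raise PanelValidationError(f"duplicate columns in {path}")
    if df.empty:
        raise PanelValidationError(f"empty panel: {path} has a header but no rows")

    entries = []
    for idx, row in df.iterrows():
        raw = row[cols["activity_percent"]]
        activity = pd.to_numeric(raw, errors="coerce")
        if pd.isna(activity):
            raise PanelValidationError(
                f"row {idx + 2} of {path.name}: activity {raw!r} is not numeric"
            )
        group = row.get(cols["group_key"], "")
        if pd.isna(group):
            group = ""
        try:
            entries.append(
                PanelEntry(
                    kinase_name=str(row[cols["kinase"]]),
                    activity_percent=float(activity),
                    group_key=str(group),
                    is_reference_target=_parse_bool(
                        row.get(cols["is_reference_target"], False)
                    ),
                )
            )
        except PanelValidationError as err:
            raise PanelValidationError(f"row {idx + 2} of {path.name}: {err}") from err
    return KinasePanel(
        inhibitor_name=inhibitor_name or path.stem,
        inhibitor_conc_uM=inhibitor_conc_uM,
        entries=tuple(entries),
    )


def collapse_panel(
    panel: KinasePanel,
    policy: str = "keep-named-representative",
    representatives: Mapping[str, str] | None = None,
) -> KinasePanel:
    """Collapse redundant entries so each ``group_key`` appears exactly once.

    Policies
    --------
    ``keep-first``
        Keep the first entry of each group in panel order.
    ``keep-min-activity``
        Keep the most-inhibited entry (lowest residual activity).
    ``keep-named-representative``
        Keep the entry named in *representatives* (a ``group_key -> kinase
        name`` mapping, default :data:`DEFAULT_REPRESENTATIVES`); groups
        absent from the mapping fall back to ``keep-first``.  Naming a
        representative absent from its group is an error.

    The returned panel records which entries were dropped; collapsing is
    idempotent.
    """
    if policy not in COLLAPSE_POLICIES:
        raise ValueError(f"unknown collapse policy {policy!r}; use one of {COLLAPSE_POLICIES}")
    if representatives is None:
        representatives = DEFAULT_REPRESENTATIVES

    groups: dict[str, list[PanelEntry]] = {}
    order: list[str] = []
    for entry in panel.entries:
        if entry.group_key not in groups:
            groups[entry.group_key] = []
            order.append(entry.group_key)
        groups[entry.group_key].append(entry)

    kept: list[PanelEntry] = []
    dropped: list[PanelEntry] = list(panel.dropped)
    for key in order:
        members = groups[key]
        if len(members) == 1:
            kept.append(members[0])
            continue
        if policy == "keep-min-activity":
            chosen = min(members, key=lambda e: (e.activity_percent, e.kinase_name))
        elif policy == "keep-named-representative" and key in representatives:
            name = representatives[key]
            matches = [e for e in members if e.kinase_name == name]
            if not matches:
                raise PanelValidationError(
                    f"representative {name!r} not found in group {key!r} "
                    f"(members: {[e.kinase_name for e in members]})"
                )
            chosen = matches[0]
        else:  # keep-first, or keep-named-representative without a mapping entry
            chosen = members[0]
        kept.append(chosen)
        dropped.extend(e for e in members if e is not chosen)

    if dropped[len(panel.dropped):]:
        logger.info(
            "collapse_panel dropped %d redundant entries: %s",
            len(dropped) - len(panel.dropped),
            [e.kinase_name for e in dropped[len(panel.dropped):]],
        )
    return replace(panel, entries=tuple(kept), dropped=tuple(dropped))


def write_panel(panel: KinasePanel, path: str | Path) -> None:
    """Write a panel to CSV in the canonical dialect (UTF-8, header).

    Round-trip contract: ``read_panel(write_panel(p))`` reproduces every
    (kinase_name, activity_percent, group_key, is_reference_target) tuple.
    """
    path = Path(path)
    df = panel.to_frame()
    # keep group_key column sparse: blank where it just repeats the name
    df["group_key"] = [
        "" if e.group_key == e.kinase_name else e.group_key for e in panel.entries
    ]
    df["is_reference_target"] = [
        "true" if e.is_reference_target else "" for e in panel.entries
    ]
    df.to_csv(path, index=False, encoding="utf-8")


def _load_fixture(name: str, inhibitor: str) -> KinasePanel:
    ref = resources.files("kinselect.data").joinpath(name)
    with resources.as_file(ref) as p:
        return read_panel(p, inhibitor_name=inhibitor, inhibitor_conc_uM=1.0)


def load_quinalizarin_panel(collapsed: bool = False) -> KinasePanel:
    """The packaged 141-row quinalizarin panel (1 µM, residual activity %).

    With ``collapsed=True`` the two CK2 rows (holoenzyme α₂β₂ and isolated
    α) are merged to the holoenzyme entry, giving the 140-kinase panel on
    which the selectivity statistics are defined.
    """
    panel = _load_fixture("quinalizarin_table1.csv", "quinalizarin")
    if collapsed:
        panel = collapse_panel(panel)
    return panel


def load_ck2_forms() -> KinasePanel:
    """Residual activities of six CK2 forms at 1 µM quinalizarin."""
    return _load_fixture("quinalizarin_table3.csv", "quinalizarin")
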