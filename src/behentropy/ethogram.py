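"""Ethogram: the catalogue of scored behavior categories.

The ethogram defines the state space of the behavior jump chain. Labels are
ordered; the integer code of a label is its position in that order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import FormatError

#: Default six-state maternal-care ethogram. The first three are the
#: nurturing behaviors typically scored in rodent dam observations
#: (licking/grooming, arched-back nursing, other/passive nursing); the rest
#: fill out a realistic repertoire of non-nurturing states.
DEFAULT_LABELS = (
    "lick_groom",
    "arched_nurse",
    "passive_nurse",
    "off_nest",
    "eat_drink",
    "nest_build",
)


@dataclass(frozen=True)
class Ethogram:
    """Ordered set of behavior labels.

    Parameters
    ----------
    labels
        Unique behavior names. Order is meaningful: state ``i`` of every
        transition matrix is ``labels[i]``.
    """

    labels: tuple[str, ...]
    codes: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        labels = tuple(self.labels)
        if len(labels) < 2:
            raise FormatError(
                f"an ethogram needs at least 2 behaviors, got {len(labels)}"
            )
        if len(set(labels)) != len(labels):
            dupes = sorted({b for b in labels if labels.count(b) > 1})
            raise FormatError(f"duplicate behavior labels: {dupes}")
        if any(not isinstance(b, str) or not b for b in labels):
            raise FormatError("behavior labels must be non-empty strings")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "codes", {b: i for i, b in enumerate(labels)})

    @property
    def k(self) -> int:
        """Number of states."""
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.codes

    def __iter__(self):
        return iter(self.labels)

    def code(self, label: str) -> int:
        try:
            return self.codes[label]
        except KeyError:
            raise FormatError(f"behavior {label!r} is not in the ethogram") from None


def default_ethogram() -> Ethogram:
    """Return the built-in six-state maternal-care ethogram."""
    return Ethogram(DEFAULT_LABELS)


def read_ethogram(source) -> Ethogram:
    """Read an ethogram from a YAML/JSON file path, text, or list of labels.

    The on-disk format is simply a list of label strings (YAML is a superset
    of JSON, so both parse).
    """
    if isinstance(source, Ethogram):
        return source
    if isinstance(source, (list, tuple)):
        return Ethogram(tuple(source))
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise FormatError(f"cannot parse ethogram: {exc}") from exc
    if not isinstance(data, list):
        raise FormatError("ethogram file must contain a list of behavior labels")
    return Ethogram(tuple(str(b) for b in data))


def write_ethogram(ethogram: Ethogram, path, fmt: str = "yaml") -> None:
    """Write an ethogram as a YAML or JSON list of labels."""
    labels = list(ethogram.labels)
    if fmt == "json":
        Path(path).write_text(json.dumps(labels, indent=2) + "\n")
    else:
        Path(path).write_text(yaml.safe_dump(labels, default_flow_style=False))
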