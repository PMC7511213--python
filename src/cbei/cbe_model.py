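"""Cytosine base editor targeting models.

A :class:`CbeModel` captures everything the spacer search needs to know
about an editor: the PAM pattern (IUPAC, e.g. NGG, NG, NNGRRT, TTTV,
NGCG) and which side of the protospacer it sits on, the spacer length,
and the editing window.  Window positions are counted 1-based from the
5' end of the protospacer as written 5'->3' on its own strand — the
convention under which "position 6" is the sole editable base of
YEE-BE3 — and the same numbering applies to 5'-PAM (Cas12a) editors.

Thirteen presets cover the commonly used CBEs.  Spacer lengths and
editing windows not fixed by the PAM chemistry are taken from the primary
characterization literature for each editor (Komor 2016; Kim 2017,
narrow-window and altered-PAM variants; Hu 2018, xCas9; Jiang 2018,
BE-PLUS; Nishida 2016 and Nishimasu 2018, Target-AID; Li 2018,
dCas12a-BE).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "CbeModel", "PamMatcher", "iupac_to_matcher",
    "load_preset", "preset_names", "load_custom_model",
    "DEFAULT_CONTEXT_ORDER", "IUPAC_CODES",
]

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Activity preference by the base 5' of the edited C, best first.
DEFAULT_CONTEXT_ORDER: tuple[str, ...] = ("TC", "CC", "AC", "GC")


@dataclass(frozen=True)
class PamMatcher:
    """Exact matcher for the concrete expansions of an IUPAC pattern.

    Strings containing N never match: an ambiguous genomic base cannot be
    trusted to satisfy a PAM requirement.
    """

    pattern: str
    _regex: re.Pattern = field(repr=False, compare=False, default=None)

    def matches(self, s: str) -> bool:
        return len(s) == len(self.pattern) and self._regex.fullmatch(s) is not None

    def __len__(self) -> int:
        return len(self.pattern)


def iupac_to_matcher(pattern: str) -> PamMatcher:
    """Compile an IUPAC degenerate DNA pattern into a PamMatcher."""
    if not pattern:
        raise ValueError("empty PAM pattern")
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC_CODES:
            raise ValueError(f"illegal IUPAC letter {ch!r} in pattern {pattern!r}")
        allowed = IUPAC_CODES[ch]
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    return PamMatcher(pattern=pattern.upper(), _regex=re.compile("".join(parts)))


@dataclass(frozen=True)
class CbeModel:
    """Targeting rules for one cytosine base editor."""

    name: str
    pam_pattern: str
    pam_side: str  # "3prime" (Cas9-family) or "5prime" (Cas12a)
    spacer_len: int
    window_start: int
    window_end: int
    context_order: tuple[str, ...] = DEFAULT_CONTEXT_ORDER

    def __post_init__(self) -> None:
        if self.pam_side not in ("3prime", "5prime"):
            raise ValueError(f"pam_side must be '3prime' or '5prime', got {self.pam_side!r}")
        if not (1 <= self.window_start <= self.window_end <= self.spacer_len):
            raise ValueError(
                f"{self.name}: editing window {self.window_start}-{self.window_end} "
                f"must satisfy 1 <= start <= end <= spacer_len ({self.spacer_len})"
            )
        # validates the pattern eagerly
        iupac_to_matcher(self.pam_pattern)

    @property
    def pam_matcher(self) -> PamMatcher:
        return iupac_to_matcher(self.pam_pattern)

    @property
    def pam_len(self) -> int:
        return len(self.pam_pattern)

    def window_positions(self) -> list[int]:
        """Inclusive editing-window positions, 1-based from the protospacer 5' end."""
        return list(range(self.window_start, self.window_end + 1))


def _m(name, pam, side, spacer, w0, w1) -> CbeModel:
    return CbeModel(
        name=name, pam_pattern=pam, pam_side=side,
        spacer_len=spacer, window_start=w0, window_end=w1,
    )


#: The 13 built-in editor presets.
PRESETS: dict[str, CbeModel] = {
    m.name: m
    for m in [
        _m("BE3", "NGG", "3prime", 20, 4, 8),           # Komor 2016
        _m("xBE3", "NG", "3prime", 20, 4, 8),           # Hu 2018 (xCas9-BE3)
        _m("BE-PLUS", "NGG", "3prime", 20, 4, 14),      # Jiang 2018
        _m("SaBE3", "NNGRRT", "3prime", 21, 3, 12),     # Kim 2017
        _m("Sa(KKH)-BE3", "NNNRRT", "3prime", 21, 3, 12),  # Kim 2017
        _m("VQR-BE3", "NGAN", "3prime", 20, 4, 11),     # Kim 2017
        _m("VRER-BE3", "NGCG", "3prime", 20, 3, 10),    # Kim 2017
        _m("YE1-BE3", "NGG", "3prime", 20, 5, 7),       # Kim 2017 (narrowed window)
        _m("EE-BE3", "NGG", "3prime", 20, 5, 6),        # Kim 2017
        _m("YEE-BE3", "NGG", "3prime", 20, 6, 6),       # Kim 2017 (position 6 only)
        _m("Target-AID", "NGG", "3prime", 20, 2, 4),    # Nishida 2016
        _m("Target-AID-NG", "NG", "3prime", 20, 2, 4),  # Nishimasu 2018
        _m("Cas12a-BE", "TTTV", "5prime", 23, 8, 13),   # Li 2018 (dCas12a)
    ]
}


def _norm_name(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", name.lower())


_ALIASES = {_norm_name(k): k for k in PRESETS}


def preset_names() -> list[str]:
    """Names of the built-in presets, in registry order."""
    return list(PRESETS)


def load_preset(name: str) -> CbeModel:
    """Look up a built-in CBE preset, alias-insensitively (``SaKKH-BE3`` == ``Sa(KKH)-BE3``)."""
    key = _ALIASES.get(_norm_name(name))
    if key is None:
        raise ValueError(f"unknown CBE preset {name!r}; available: {', '.join(PRESETS)}")
    return PRESETS[key]


def load_custom_model(path: Union[str, Path]) -> CbeModel:
    """Load a custom editor from a YAML/JSON config with the preset fields.

    Required keys: name, pam_pattern, pam_side, spacer_len, window_start,
    window_end; optional: context_order.
    """
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of CbeModel fields")
    if "context_order" in data:
        data["context_order"] = tuple(data["context_order"])
    try:
        return CbeModel(**data)
    except TypeError as exc:
        raise ValueError(f"{path}: {exc}") from None
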