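"""Cas enzyme / PAM registry.

Each entry records the PAM motifs an enzyme recognises, the PAM's position
relative to the protospacer (class II nucleases read their PAM immediately 3'
of the protospacer; class V immediately 5'), the default spacer length, and
whether the enzyme is a natural ortholog or an engineered PAM-relaxed variant.

``primary_motifs`` generate candidate matches on the variant allele;
``off_target_motifs`` (e.g. NAG for SpCas9) are suboptimal PAMs the enzyme can
still engage — they never generate candidates but, found on the reference
allele at the locus, they defeat allele specificity and veto the candidate.
"""

from __future__ import annotations

import configparser
import io as _io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional, Sequence

from .errors import RegistryError
from .sequence import PamMotif


class CasClass(str, Enum):
    II = "II"
    V = "V"


class PamOrientation(str, Enum):
    #: PAM lies 3' of the protospacer (Cas9-type enzymes).
    downstream_of_protospacer = "downstream"
    #: PAM lies 5' of the protospacer (Cas12a-type enzymes).
    upstream_of_protospacer = "upstream"


class CasOrigin(str, Enum):
    natural = "natural"
    synthetic = "synthetic"


_CLASS_TO_ORIENTATION = {
    CasClass.II: PamOrientation.downstream_of_protospacer,
    CasClass.V: PamOrientation.upstream_of_protospacer,
}

#: Canonical spacer lengths by class: 20 nt for Cas9-family (class II),
#: 23 nt for Cas12a-family (class V).
DEFAULT_SPACER_LENGTH = {CasClass.II: 20, CasClass.V: 23}


@dataclass(frozen=True)
class CasEnzyme:
    name: str
    cas_class: CasClass
    primary_motifs: tuple[PamMotif, ...]
    off_target_motifs: tuple[PamMotif, ...] = ()
    spacer_length: int = 0
    origin: CasOrigin = CasOrigin.natural
    approx_size_bp: Optional[int] = None  # metadata only, never used in logic

    def __post_init__(self) -> None:
        if not self.primary_motifs:
            raise RegistryError(f"enzyme {self.name!r}: at least one primary motif required")
        if self.spacer_length <= 0:
            object.__setattr__(
                self, "spacer_length", DEFAULT_SPACER_LENGTH[self.cas_class]
            )
        for motifs, label in (
            (self.primary_motifs, "primary"),
            (self.off_target_motifs, "off-target"),
        ):
            patterns = [m.pattern for m in motifs]
            if len(patterns) != len(set(patterns)):
                raise RegistryError(
                    f"enzyme {self.name!r}: duplicate {label} motif patterns"
                )

    @property
    def pam_orientation(self) -> PamOrientation:
        return _CLASS_TO_ORIENTATION[self.cas_class]

    @property
    def rejection_motifs(self) -> tuple[PamMotif, ...]:
        """Motifs checked against the reference allele: primary + off-target."""
        return self.primary_motifs + self.off_target_motifs


@dataclass(frozen=True)
class CasRegistry:
    """An ordered, name-unique collection of Cas enzymes (value semantics)."""

    enzymes: tuple[CasEnzyme, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [e.name for e in self.enzymes]
        if len(names) != len(set(names)):
            raise RegistryError("registry enzyme names must be unique")

    def __iter__(self) -> Iterator[CasEnzyme]:
        return iter(self.enzymes)

    def __len__(self) -> int:
        return len(self.enzymes)

    def __contains__(self, name: str) -> bool:
        return any(e.name == name for e in self.enzymes)

    def get(self, name: str) -> CasEnzyme:
        for e in self.enzymes:
            if e.name == name:
                return e
        raise KeyError(name)

    def names(self) -> list[str]:
        return [e.name for e in self.enzymes]

    def distinct_primary_patterns(self) -> set[str]:
        return {m.pattern for e in self.enzymes for m in e.primary_motifs}

    def without(self, name: str) -> "CasRegistry":
        return CasRegistry(tuple(e for e in self.enzymes if e.name != name))


def _motifs(*patterns: str) -> tuple[PamMotif, ...]:
    return tuple(PamMotif(p) for p in patterns)


def _e(
    name: str,
    cas_class: CasClass,
    primary: Sequence[str],
    off_target: Sequence[str] = (),
    origin: CasOrigin = CasOrigin.natural,
    size: Optional[int] = None,
) -> CasEnzyme:
    return CasEnzyme(
        name=name,
        cas_class=cas_class,
        primary_motifs=_motifs(*primary),
        off_target_motifs=_motifs(*off_target),
        origin=origin,
        approx_size_bp=size,
    )


_SYN = CasOrigin.synthetic
_II = CasClass.II
_V = CasClass.V


def builtin_registry() -> CasRegistry:
    """The built-in table: 23 enzymes (AsCas12a and LbCas12a share one entry,
    both recognising TTTN) spanning 26 distinct primary PAM patterns."""
    return CasRegistry(
        (
            _e("SpCas9", _II, ["NGG"], off_target=["NAG"], size=4100),
            _e("VRER SpCas9", _II, ["NGCG"], origin=_SYN),
            _e("EQR SpCas9", _II, ["NGAG"], origin=_SYN),
            _e("VQR SpCas9", _II, ["NGAN"], origin=_SYN),
            _e("SpCas9-NG", _II, ["NG", "NANG"], origin=_SYN),
            _e("xCas9", _II, ["NG"], origin=_SYN),
            _e("SpCas9-NRRH", _II, ["NRRH", "NGGN"], origin=_SYN),
            _e("SpCas9-NRTH", _II, ["NRTH", "NGGN"], origin=_SYN),
            _e("SpCas9-NRCH", _II, ["NRCH", "NGGN"], origin=_SYN),
            _e("SaCas9", _II, ["NNGRRT"], size=3150),
            _e("KKH SaCas9", _II, ["NNNRRT"], origin=_SYN),
            _e("NmCas9", _II, ["NNNNGATT"], size=3240),
            _e("St1Cas9", _II, ["NNRGAAW"], size=4180),
            _e("St3Cas9", _II, ["NGGNG"]),
            _e("TdCas9", _II, ["NAAAAC"], size=4200),
            _e("CjCas9", _II, ["NNNVRYM"], size=2950),
            _e("SpCas9-Spa", _II, ["NNGTGA"], size=3400),
            _e("AsCas12a/LbCas12a", _V, ["TTTN"], size=3685),
            _e("AsCas12a RVR", _V, ["TATV"], origin=_SYN),
            _e("AsCas12a RR", _V, ["TYCV"], origin=_SYN),
            _e("enAsCas12a", _V, ["TGTV", "VTTV", "TTTT", "TTCN"], origin=_SYN),
            _e("FnCas12a", _V, ["TTV"], size=3900),
            _e("Cas12e", _V, ["TTCN"], size=2940),
        )
    )


def register_custom(
    registry: CasRegistry,
    name: str,
    motifs: Iterable[str],
    orientation: PamOrientation | CasClass | str,
    spacer_length: int,
) -> CasRegistry:
    """Return a new registry with a user-defined enzyme appended.

    ``orientation`` may be given as a PamOrientation, a CasClass, or the
    strings "downstream"/"upstream"/"II"/"V". The original registry is left
    unmodified. New entries are marked synthetic.
    """
    if name in registry:
        raise RegistryError(f"enzyme name {name!r} already registered")
    if spacer_length < 1:
        raise RegistryError(f"spacer_length must be >= 1, got {spacer_length}")
    if isinstance(orientation, CasClass):
        cas_class = orientation
    elif isinstance(orientation, PamOrientation):
        cas_class = (
            _II if orientation is PamOrientation.downstream_of_protospacer else _V
        )
    else:
        key = str(orientation).lower()
        if key in ("downstream", "ii", "2"):
            cas_class = _II
        elif key in ("upstream", "v", "5"):
            cas_class = _V
        else:
            raise RegistryError(f"unknown PAM orientation {orientation!r}")
    enzyme = CasEnzyme(
        name=name,
        cas_class=cas_class,
        primary_motifs=_motifs(*motifs),
        spacer_length=spacer_length,
        origin=_SYN,
    )
    return CasRegistry(registry.enzymes + (enzyme,))


# ---------------------------------------------------------------------------
# Plain-text config serialization (one enzyme per stanza)

def registry_to_config(registry: CasRegistry) -> str:
    cp = configparser.ConfigParser()
    cp.optionxform = str  # keep case
    for e in registry:
        cp[e.name] = {
            "class": e.cas_class.value,
            "pams": ",".join(m.pattern for m in e.primary_motifs),
            "off_target_pams": ",".join(m.pattern for m in e.off_target_motifs),
            "spacer_length": str(e.spacer_length),
            "origin": e.origin.value,
            "size_bp": "" if e.approx_size_bp is None else str(e.approx_size_bp),
        }
    buf = _io.StringIO()
    cp.write(buf)
    return buf.getvalue()


def registry_from_config(text: str) -> CasRegistry:
    cp = configparser.ConfigParser()
    cp.optionxform = str
    cp.read_string(text)
    enzymes = []
    for name in cp.sections():
        sec = cp[name]
        off = sec.get("off_target_pams", "")
        size = sec.get("size_bp", "")
        enzymes.append(
            CasEnzyme(
                name=name,
                cas_class=CasClass(sec["class"]),
                primary_motifs=_motifs(*sec["pams"].split(",")),
                off_target_motifs=_motifs(*off.split(",")) if off else (),
                spacer_length=int(sec["spacer_length"]),
                origin=CasOrigin(sec["origin"]),
                approx_size_bp=int(size) if size else None,
            )
        )
    return CasRegistry(tuple(enzymes))
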