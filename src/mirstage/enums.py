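"""Controlled vocabularies shared across the pipeline."""

from __future__ import annotations

import enum

from .errors import ValidationError


class Direction(str, enum.Enum):
    """Direction of expressional dysregulation (disease vs control)."""

    UP = "up"
    DOWN = "down"

    @property
    def opposite(self) -> "Direction":
        return Direction.DOWN if self is Direction.UP else Direction.UP

    @classmethod
    def parse(cls, token: str) -> "Direction":
        try:
            return cls(token.strip().lower())
        except ValueError:
            raise ValidationError(
                f"unknown direction {token!r}; expected one of {[d.value for d in cls]}"
            ) from None


class Source(str, enum.Enum):
    """Biospecimen source of a dysregulation report.

    Unknown source strings are rejected, never coerced. The TSV token
    ``saliva_exosome`` maps to SALIVA with an exosome flag on the record,
    not to a separate enum member.
    """

    TISSUE = "tissue"
    SALIVA = "saliva"
    BLOOD = "blood"
    CELL_LINE = "cell_line"
    EXOSOME = "exosome"

    @classmethod
    def parse(cls, token: str) -> tuple["Source", bool]:
        """Parse a source token, returning (source, exosome_flag)."""
        clean = token.strip().lower()
        if clean == "saliva_exosome":
            return cls.SALIVA, True
        try:
            return cls(clean), False
        except ValueError:
            allowed = [s.value for s in cls] + ["saliva_exosome"]
            raise ValidationError(
                f"unknown sample source {token!r}; expected one of {allowed}"
            ) from None


#: Sources admissible for the direction filter by default.
DEFAULT_ALLOWED_SOURCES: frozenset[Source] = frozenset({Source.TISSUE, Source.SALIVA})


class Stage(str, enum.Enum):
    """Histological stage of early oral oncogenesis."""

    HYPERPLASIA = "hyperplasia"
    DYSPLASIA = "dysplasia"
    EARLY_INVASION = "early_invasion"

    @classmethod
    def parse(cls, token: str) -> "Stage":
        clean = token.strip().lower().replace("-", "_").replace(" ", "_")
        try:
            return cls(clean)
        except ValueError:
            raise ValidationError(
                f"unknown stage {token!r}; allowed stages: {[s.value for s in cls]}"
            ) from None


#: Canonical stage ordering along the oncogenic sequence.
STAGE_ORDER: tuple[Stage, ...] = (
    Stage.HYPERPLASIA,
    Stage.DYSPLASIA,
    Stage.EARLY_INVASION,
)


class Qualifier(str, enum.Enum):
    """Consistency label attached to a direction verdict."""

    CONSISTENT = "consistent"
    MOSTLY = "mostly"
    RARELY = "rarely"
    NONE = "none"


class SiteType(enum.IntEnum):
    """Canonical seed-site classes, ordered by increasing specificity."""

    SITE_6MER = 1
    SITE_7MER_A1 = 2
    SITE_7MER_M8 = 3
    SITE_8MER = 4

    @property
    def span(self) -> int:
        """Length of the site interval on the UTR."""
        return {self.SITE_6MER: 6, self.SITE_7MER_A1: 7, self.SITE_7MER_M8: 7, self.SITE_8MER: 8}[self]
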