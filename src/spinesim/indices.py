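"""Per-case clinical indices: the quantities read off standing and
side-bending radiographs for one AIS (adolescent idiopathic scoliosis)
patient — curve levels, regional coronal Cobb angles, bending Cobb angles,
apical vertebral rotations, kyphosis, lordosis and the instrumented levels.

The case-table schema uses exactly these field names as CSV columns, angles
as plain numbers in degrees.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

from . import levels

__all__ = ["ClinicalIndices", "SCHEMA_COLUMNS"]

#: required case-table columns, in canonical order
SCHEMA_COLUMNS = [
    "case_id", "sex", "age", "height", "weight", "lenke",
    "pt_sup_end", "mt_sup_end", "mt_apex", "mt_inf_end",
    "pt_cobb", "mt_cobb", "tll_cobb",
    "pt_bend_left", "pt_bend_right", "mt_bend_left", "mt_bend_right",
    "tll_bend_left", "tll_bend_right",
    "mt_avr", "tll_avr", "kyphosis", "lordosis", "uiv", "liv",
]

_ANGLE_FIELDS = ["pt_cobb", "mt_cobb", "tll_cobb", "pt_bend_left",
                 "pt_bend_right", "mt_bend_left", "mt_bend_right",
                 "tll_bend_left", "tll_bend_right", "mt_avr", "tll_avr",
                 "kyphosis", "lordosis"]
_LEVEL_FIELDS = ["pt_sup_end", "mt_sup_end", "mt_apex", "mt_inf_end",
                 "uiv", "liv"]


@dataclass
class ClinicalIndices:
    """One case-table row; angles in degrees, height cm, weight kg."""

    case_id: str
    sex: str
    age: float
    height: float
    weight: float
    lenke: str
    pt_sup_end: str
    mt_sup_end: str
    mt_apex: str
    mt_inf_end: str
    pt_cobb: float
    mt_cobb: float
    tll_cobb: float
    pt_bend_left: float
    pt_bend_right: float
    mt_bend_left: float
    mt_bend_right: float
    tll_bend_left: float
    tll_bend_right: float
    mt_avr: float
    tll_avr: float
    kyphosis: float
    lordosis: float
    uiv: str
    liv: str
    #: convexity of the main thoracic curve; proximal thoracic and
    #: thoracolumbar/lumbar curves are taken convex to the opposite side
    #: (typical right-thoracic pattern).  Not printed per case; configurable.
    mt_convexity: str = "right"
    #: inferior end vertebra of the TL/L curve (not printed; standard default)
    tll_inf_end: str = "L4"

    @property
    def tll_apex(self) -> str:
        return levels.midpoint(self.mt_inf_end, self.tll_inf_end)

    @property
    def pt_apex(self) -> str:
        return levels.midpoint(self.pt_sup_end, self.mt_sup_end)

    @property
    def fused_levels(self) -> list:
        return levels.span(self.uiv, self.liv)

    def convexity(self, region: str) -> str:
        """'left' or 'right' convexity of region in {'PT','MT','TLL'}."""
        other = "left" if self.mt_convexity == "right" else "right"
        return self.mt_convexity if region == "MT" else other

    def region_span(self, region: str) -> tuple:
        """(upper end, lower end) measurement levels of a coronal region."""
        return {
            "PT": (self.pt_sup_end, self.mt_sup_end),
            "MT": (self.mt_sup_end, self.mt_inf_end),
            "TLL": (self.mt_inf_end, self.tll_inf_end),
        }[region]

    def validate(self) -> "ClinicalIndices":
        for f in _LEVEL_FIELDS + ["tll_inf_end"]:
            lab = getattr(self, f)
            if not levels.is_valid(lab):
                raise ValueError(f"{f}: invalid level label {lab!r}")
        for f in _ANGLE_FIELDS:
            if float(getattr(self, f)) < 0:
                raise ValueError(f"{f}: Cobb/rotation angles must be >= 0 "
                                 f"(got {getattr(self, f)})")
        if not (levels.cephalad_of(self.mt_sup_end, self.mt_apex)
                and levels.cephalad_of(self.mt_apex, self.mt_inf_end)):
            raise ValueError(
                "mt_apex: apex must lie strictly between the superior and "
                f"inferior end vertebrae (got {self.mt_sup_end} / "
                f"{self.mt_apex} / {self.mt_inf_end})")
        if not levels.cephalad_of(self.pt_sup_end, self.mt_sup_end):
            raise ValueError("pt_sup_end: must be cephalad of mt_sup_end")
        if not levels.cephalad_of(self.mt_inf_end, self.tll_inf_end):
            raise ValueError("tll_inf_end: must be caudal of mt_inf_end")
        if not levels.cephalad_of(self.uiv, self.liv):
            raise ValueError(f"uiv: UIV ({self.uiv}) must be cephalad of "
                             f"LIV ({self.liv})")
        if self.mt_convexity not in ("left", "right"):
            raise ValueError("mt_convexity: must be 'left' or 'right'")
        if not (120.0 <= float(self.height) <= 200.0):
            raise ValueError(f"height: expected 120-200 cm, got {self.height}")
        return self

    def to_dict(self) -> dict:
        return asdict(self)
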