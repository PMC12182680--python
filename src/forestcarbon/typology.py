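"""Forest typology: integer codes for forest types plus the non-forest code.

The study groups field records into primary forest types (e.g. ENF, DNF,
EBF, DBF, MF, possibly split by climatic zone). The mapping from finer
sub-types to primary types is a configuration input, never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import TypologyError


@dataclass(frozen=True)
class Typology:
    """Forest type codes. ``codes`` are the forest types; ``non_forest`` is
    the single background code (conventionally 0).

    ``sub_to_primary`` optionally maps finer sub-type codes onto the primary
    codes used for growth fitting; every sub-type maps to exactly one primary.
    """

    codes: tuple[int, ...]
    names: dict[int, str] = field(default_factory=dict)
    non_forest: int = 0
    sub_to_primary: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.codes) < 1:
            raise TypologyError("typology needs at least one forest type")
        if self.non_forest in self.codes:
            raise TypologyError("non-forest code collides with a forest code")
        if len(set(self.codes)) != len(self.codes):
            raise TypologyError("duplicate forest codes")
        bad = set(self.sub_to_primary.values()) - set(self.codes)
        if bad:
            raise TypologyError(f"sub-types map to unknown primary codes {sorted(bad)}")

    @property
    def all_codes(self) -> tuple[int, ...]:
        return (self.non_forest,) + self.codes

    def is_forest(self, code: int) -> bool:
        return code in self.codes

    def name(self, code: int) -> str:
        if code == self.non_forest:
            return "non-forest"
        return self.names.get(code, f"type{code}")

    def primary(self, sub_code: int) -> int:
        """Primary type of a sub-type code (identity if already primary)."""
        if sub_code in self.codes or sub_code == self.non_forest:
            return sub_code
        try:
            return self.sub_to_primary[sub_code]
        except KeyError:
            raise TypologyError(f"unknown code {sub_code}") from None


def default_typology(n_types: int = 5) -> Typology:
    names = {1: "ENF", 2: "DNF", 3: "EBF", 4: "DBF", 5: "MF"}
    codes = tuple(range(1, n_types + 1))
    return Typology(codes=codes, names={c: names.get(c, f"type{c}") for c in codes})
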