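"""Condition catalog: condition code -> ICPC-2 chapter + chronic flag.

The chapters of ICPC-2 (International Classification of Primary Care, v2)
serve as body-system proxies throughout the package: multimorbidity counting
collapses conditions to chapters, and complex multimorbidity requires
conditions spread over three or more chapters.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

#: The 17 one-letter ICPC-2 chapter codes (body systems / problem areas).
ICPC2_CHAPTERS: frozenset[str] = frozenset(
    "A B D F H K L N P R S T U W X Y Z".split()
)

ICPC2_CHAPTER_LABELS: dict[str, str] = {
    "A": "General and unspecified",
    "B": "Blood, blood-forming organs and immune mechanism",
    "D": "Digestive",
    "F": "Eye",
    "H": "Ear",
    "K": "Circulatory",
    "L": "Musculoskeletal",
    "N": "Neurological",
    "P": "Psychological",
    "R": "Respiratory",
    "S": "Skin",
    "T": "Endocrine, metabolic and nutritional",
    "U": "Urology",
    "W": "Pregnancy, childbearing, family planning",
    "X": "Female genital",
    "Y": "Male genital",
    "Z": "Social problems",
}


class UnknownConditionError(KeyError):
    """A condition code absent from the catalog was used."""


@dataclass(frozen=True)
class CatalogEntry:
    code: str
    label: str
    icpc2_chapter: str
    chronic: bool


@dataclass
class ConditionCatalog:
    """Lookup table driving chapter assignment and chronic-condition counting.

    Lookup of an unknown code raises :class:`UnknownConditionError`; there is
    deliberately no silent default, so typos in input files surface as errors.
    """

    entries: dict[str, CatalogEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, entry in self.entries.items():
            if entry.icpc2_chapter not in ICPC2_CHAPTERS:
                raise ValueError(
                    f"condition {code!r}: {entry.icpc2_chapter!r} is not an "
                    f"ICPC-2 chapter code"
                )

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def entry(self, code: str) -> CatalogEntry:
        try:
            return self.entries[code]
        except KeyError:
            raise UnknownConditionError(
                f"condition code {code!r} is not in the catalog"
            ) from None

    def chapter(self, code: str) -> str:
        return self.entry(code).icpc2_chapter

    def is_chronic(self, code: str) -> bool:
        return self.entry(code).chronic

    def chronic_subset(self, codes) -> frozenset[str]:
        """The chronic conditions among ``codes`` (validates every code)."""
        return frozenset(c for c in codes if self.is_chronic(c))

    def chronic_codes(self) -> frozenset[str]:
        return frozenset(c for c, e in self.entries.items() if e.chronic)

    def chapter_codes(self, chapter: str, chronic_only: bool = True) -> frozenset[str]:
        if chapter not in ICPC2_CHAPTERS:
            raise ValueError(f"{chapter!r} is not an ICPC-2 chapter code")
        return frozenset(
            c
            for c, e in self.entries.items()
            if e.icpc2_chapter == chapter and (e.chronic or not chronic_only)
        )

    def validate_codes(self, codes, row: int | None = None) -> None:
        for c in codes:
            if c not in self.entries:
                where = f" (row {row})" if row is not None else ""
                raise UnknownConditionError(
                    f"condition code {c!r} is not in the catalog{where}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "code": e.code,
                    "label": e.label,
                    "icpc2_chapter": e.icpc2_chapter,
                    "chronic": e.chronic,
                }
                for e in self.entries.values()
            ]
        )


def _catalog_from_frame(df: pd.DataFrame) -> ConditionCatalog:
    required = {"code", "label", "icpc2_chapter", "chronic"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalog is missing columns: {sorted(missing)}")
    entries: dict[str, CatalogEntry] = {}
    for _, row in df.iterrows():
        code = str(row["code"]).strip()
        if code in entries:
            raise ValueError(f"duplicate condition code {code!r} in catalog")
        chronic = row["chronic"]
        if isinstance(chronic, str):
            chronic = chronic.strip().lower() in {"true", "1", "yes", "y"}
        entries[code] = CatalogEntry(
            code=code,
            label=str(row["label"]),
            icpc2_chapter=str(row["icpc2_chapter"]).strip().upper(),
            chronic=bool(chronic),
        )
    return ConditionCatalog(entries)


def load_catalog(path: str | Path) -> ConditionCatalog:
    """Load a catalog from CSV (columns code,label,icpc2_chapter,chronic) or YAML."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return _catalog_from_frame(pd.DataFrame(data))
    return _catalog_from_frame(pd.read_csv(path))


# Default catalog: the common diagnosed chronic conditions reported in
# Australian general-practice prevalence work, with their ICPC-2 chapters,
# plus a few acute (non-chronic) codes so encounter-managed problem lists can
# contain both. The code -> chapter assignment follows the conventional
# chapter groupings (circulatory K, musculoskeletal L, endocrine/metabolic T,
# psychological P, digestive D, respiratory R, neoplasms A) and is an
# approximation of any one study's full internal map.
_DEFAULT_CATALOG_CSV = """\
code,label,icpc2_chapter,chronic
hypertension,Hypertension,K,true
ischaemic_heart_disease,Ischaemic heart disease,K,true
cerebrovascular_accident,Cerebrovascular accident (stroke),K,true
congestive_heart_failure,Congestive heart failure,K,true
peripheral_vascular_disease,Peripheral vascular disease,K,true
osteoarthritis,Osteoarthritis,L,true
rheumatoid_arthritis,Rheumatoid arthritis,L,true
arthritis_other,Other and unknown arthritis,L,true
chronic_back_pain,Chronic back pain,L,true
osteoporosis,Osteoporosis,L,true
hyperlipidaemia,Hyperlipidaemia,T,true
diabetes_type1,Diabetes mellitus type 1,T,true
diabetes_type2,Diabetes mellitus type 2,T,true
depression,Depression,P,true
anxiety,Anxiety,P,true
insomnia,Chronic insomnia,P,true
dementia,Dementia,P,true
gord,Gastro-oesophageal reflux disease,D,true
asthma,Asthma,R,true
copd,Chronic obstructive pulmonary disease,R,true
malignant_neoplasm,Malignant neoplasm,A,true
chronic_kidney_disease,Chronic kidney disease,U,true
epilepsy,Epilepsy,N,true
acute_urti,Acute upper respiratory tract infection,R,false
acute_gastroenteritis,Acute gastroenteritis,D,false
contact_dermatitis,Contact dermatitis,S,false
acute_injury,Acute injury,L,false
"""


def default_catalog() -> ConditionCatalog:
    """The packaged default condition catalog."""
    return _catalog_from_frame(pd.read_csv(io.StringIO(_DEFAULT_CATALOG_CSV)))
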