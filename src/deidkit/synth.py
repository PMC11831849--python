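"""Seeded generator of bilingual radiology-style clinical notes with gold
PHI annotations.

The generator is the ground-truth authority: gold spans are written down at
assembly time, never re-derived from the rules.  Its defaults emulate the
source-data distribution the rule set was built against — roughly 10% of
notes carry PHI, dominated by dates (≈94% of PHI instances, then staff and
patient names, hospitals, regions, numbers and demographics) with slightly
more than one PHI instance per PHI-bearing note.

Three knobs shape the difficulty of the benchmark:

* ``out_of_scope_fraction`` — fraction of PHI-bearing notes written in
  notation styles the rule set does not cover (partial/relative dates,
  선생님-style name contexts, unlisted clinics, 내선-anchored numbers...).
  Notation style is an author property, so it is drawn per note; these
  notes establish the recall gap a learned tagger must close;
* ``homonym_trap_rate`` — rate of inserting non-PHI text the rules are
  known to false-positive on (고려해, 중앙값, CMC-as-anatomy, 상기확인함),
  exercising precision accounting and the corpus-correction workflow;
* ``department_mix`` — fraction of non-radiology-flavored notes.

All names, hospitals and numbers are fictitious.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .core import (
    AnnotatedNote,
    ClinicalNote,
    Department,
    PHIAnnotation,
    PHICategory,
    PersonRole,
    Span,
)
from .errors import DeidError

# Category weights mirror the source-corpus PHI-word table the rules were
# developed against (dates dominate at ~94%).
DEFAULT_CATEGORY_MIX: Dict[str, float] = {
    "DAT": 1045,
    "PER-staff": 56,
    "PER-patient": 50,
    "ORG": 47,
    "LOC": 7,
    "NUM": 3,
    "ETC": 5,
}

_MIX_KEYS: Dict[str, Tuple[PHICategory, Optional[PersonRole]]] = {
    "DAT": (PHICategory.DAT, None),
    "PER-staff": (PHICategory.PER, PersonRole.STAFF),
    "PER-patient": (PHICategory.PER, PersonRole.PATIENT),
    "ORG": (PHICategory.ORG, None),
    "LOC": (PHICategory.LOC, None),
    "NUM": (PHICategory.NUM, None),
    "ETC": (PHICategory.ETC, None),
}


@dataclass
class SynthConfig:
    seed: int = 0
    n_notes: int = 1000
    phi_note_fraction: float = 0.10
    category_mix: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CATEGORY_MIX))
    out_of_scope_fraction: float = 0.0
    department_mix: float = 0.0
    homonym_trap_rate: float = 0.0
    #: probability that a PHI-bearing note carries a second instance
    #: (source table: ~1.09 PHI words per PHI note)
    second_instance_rate: float = 0.09

    def validate(self) -> None:
        for name in (
            "phi_note_fraction",
            "out_of_scope_fraction",
            "department_mix",
            "homonym_trap_rate",
            "second_instance_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DeidError(f"{name} must be in [0, 1], got {v}")
        if self.n_notes < 0:
            raise DeidError("n_notes must be non-negative")
        if not self.category_mix:
            raise DeidError("category_mix must not be empty")
        bad = set(self.category_mix) - set(_MIX_KEYS)
        if bad:
            raise DeidError(f"unknown category_mix keys: {sorted(bad)}")
        if any(w < 0 for w in self.category_mix.values()):
            raise DeidError("category_mix weights must be non-negative")
        if not any(w > 0 for w in self.category_mix.values()):
            raise DeidError("category_mix needs at least one positive weight")


# ---------------------------------------------------------------------------
# Surface pools.  Everything here is fictitious; filler lines are curated to
# be inert under the default rule set (verified by tests).
# ---------------------------------------------------------------------------

_SURNAMES = [
    "김", "이", "박", "최", "정", "강", "조", "윤", "장", "임",
    "한", "오", "서", "신", "권", "황", "안", "송",
]
_GIVEN = [
    "민준", "서연", "도윤", "지우", "하은", "지호", "수아", "예준", "시우", "주원",
    "하준", "지민", "서준", "지윤", "채원", "지아", "은우", "유준", "서현", "민서",
    "윤서", "예은", "건우", "선우", "연우", "정우", "승현", "준서", "다은", "가은",
    "소율", "시윤", "태윤", "현우", "준혁", "도현", "민재", "규민", "세아", "윤아",
]
KOREAN_NAMES = [s + g for s in _SURNAMES for g in _GIVEN]

ENGLISH_NAMES = ["Kim Minjun", "Lee Seoyeon", "Park Doyun", "Choi Jiwoo", "Jung Haeun", "Kang Jiho"]

INITIALS = [
    "jmk", "skd", "hyl", "pjh", "kts", "mjl", "shp", "yjc", "kdh", "lsy",
    "pms", "cje", "kyh", "jsw", "hjk", "msl", "yth", "sbk", "jhl", "kmy",
    "bsn", "dhk", "ejl", "gyp", "hsc", "ijm", "jky", "kbs", "lmh", "njw",
    "osy", "pkj", "rsh", "sjp", "tkl", "uhj", "wsk", "ymp", "chj", "dkl",
]

# (weight, alias): the same institution goes by many aliases, and referrals
# name a long tail of outside hospitals and clinics — a few common surfaces
# plus many rare ones that small training samples miss.
_HOSP_PREFIXES = [
    "강북삼성", "한솔", "참튼튼", "굿모닝", "나은", "바른", "속편한", "연세사랑",
    "서울척", "힘찬", "우리들", "현대", "제일", "성심", "신촌", "마디",
    "튼튼", "선한", "미래", "햇살", "푸른", "가온", "더조은", "예손",
    "강남베드로", "시원", "큰사랑", "참좋은", "온누리", "맑은숨",
]
_CLINIC_NAMES = [
    "하나정형외과의원", "바른정형외과의원", "서울내과의원", "밝은눈의원",
    "튼튼마디의원", "속편한내과의원", "사랑가득의원", "미소가득의원",
]
_DERM_NAMES = ["미소피부과", "연세피부과", "맑은피부과", "고운피부과", "밝은피부과"]

ORG_IN_SCOPE_WEIGHTED = (
    [
        (30, "서울대병원"), (24, "본원"), (18, "연건"), (18, "고려대병원"),
        (15, "세브란스"), (15, "삼성서울병원"), (12, "서울아산병원"), (12, "고대병원"),
        (9, "서울대학교병원"), (9, "고려대학교병원"), (9, "강동성심병원"), (9, "보라매병원"),
        (6, "고대안암"), (6, "안암"), (6, "김포우리병원"), (6, "CMC"),
        (6, "분당제생병원"), (6, "중앙대학교병원"), (3, "일산백병원"), (3, "은평성모병원"),
        (3, "Samsung Medical Center"), (3, "Gangnam Severance Hospital"),
        (3, "Hallym University Hospital"),
    ]
    + [(1, p + "병원") for p in _HOSP_PREFIXES]
    + [(1, c) for c in _CLINIC_NAMES]
    + [(1, d) for d in _DERM_NAMES]
)

ORG_OUT_OF_SCOPE = [
    "SMC", "AMC", "보라매", "평촌한마음클리닉", "새봄요양센터",
    "늘푸른메디케어", "한빛정형외과", "서강신경외과", "미래영상센터",
]

LOC_IN_SCOPE = ["대구", "부산", "광주", "대전", "인천", "울산", "수원", "제주"]
LOC_OUT_OF_SCOPE = ["전주", "청주", "춘천", "Busan", "Daegu"]

NATIONALITIES = ["한국인", "미국인", "중국인", "일본인", "외국인"]

MONTH_ABBR = ["Jan", "Feb", "Mar", "Apr", "May", "Jun", "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]
MONTH_FULL = [
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
]

# Filler is deliberately rich in measurement numerals (sizes, levels,
# scores) that are rule-inert but shape-confusable with dates — the classic
# "1.2-1.7: period or medical term?" ambiguity of radiology text.
FILLER_RADIOLOGY = [
    "No significant interval change.",
    "Both lungs are clear without focal lesion.",
    "1.2-1.7 cm sized nodules in both lobes.",
    "No evidence of acute intracranial hemorrhage.",
    "Mild degenerative change of the spine.",
    "Impression: unremarkable study.",
    "특이 소견 없음.",
    "추적 관찰을 권함.",
    "간 실질의 echogenicity는 정상 범위임.",
    "Small amount of pleural effusion, right.",
    "s/p stent insertion state.",
    "췌장 및 비장은 정상 소견임.",
    "No abnormal enhancing lesion.",
    "경도의 위축성 변화가 관찰됨.",
    "Approximately 1.2 x 3.4 cm mass in segment 6.",
    "L4-5 disc space narrowing with facet arthrosis.",
    "T2 high signal intensity lesion in the pons.",
    "SUVmax 3.8 in the right hepatic lobe.",
    "Grade 2 fatty liver without focal lesion.",
    "Kidney size 10.2 cm on the right, 10.8 cm on the left.",
    "C5-6 and C6-7 foraminal stenosis, mild.",
    "EF 58% on prior echocardiography.",
    "3 x 4 mm nodule in the RUL, stable.",
    "약 2.3 cm 크기의 낭종이 관찰됨.",
    "Aorta diameter 28 mm, within normal limits.",
    "5.5 mm subcentimeter node at level 2.",
    "HU 45 on precontrast images.",
    "척추체 높이 감소 약 30% 관찰됨.",
    "ADC value 820 x 10-6 mm2/s.",
    "Exposure index 388, deviation 0.8.",
]

# Parameterized numeric furniture: accession/protocol/dose values vary per
# note, like real reports.  None of it is rule-matchable (no year-shaped
# prefix plus date separator pattern, no identifier words), but its token
# shapes collide with date notations — the discrimination a learned tagger
# must acquire from data.
_PARAM_FILLER_RADIOLOGY = [
    lambda rng: f"Accession number {rng.randint(2100, 9899)}-{rng.randint(1000, 9999)}.",
    lambda rng: f"Series {rng.randint(1, 12)}, image {rng.randint(10, 400)} of {rng.randint(100, 600)}.",
    lambda rng: f"kVp {rng.choice([80, 100, 120, 140])}, mAs {rng.randint(50, 300)}, DLP {rng.randint(100, 900)}.{rng.randint(0, 9)}.",
    lambda rng: f"Protocol {rng.randint(1, 9)}.{rng.randint(0, 9)}.{rng.randint(0, 9)} reconstruction applied.",
    lambda rng: f"{rng.randint(1, 9)}.{rng.randint(1, 9)} x {rng.randint(1, 9)}.{rng.randint(1, 9)} cm mass in segment {rng.randint(1, 8)}.",
    lambda rng: f"HU {rng.randint(20, 90)} on precontrast images.",
    lambda rng: f"WBC {rng.randint(4000, 12000)}, Hb {rng.randint(9, 16)}.{rng.randint(0, 9)}, PLT {rng.randint(150, 400)}000.",
    lambda rng: f"Room {rng.randint(1, 4)}{rng.randint(100, 999)} portable exam.",
    lambda rng: f"Kidney size {rng.randint(9, 12)}.{rng.randint(0, 9)} cm on the right.",
    lambda rng: f"EF {rng.randint(45, 70)}% on prior echocardiography.",
    lambda rng: f"SUVmax {rng.randint(1, 12)}.{rng.randint(0, 9)} in the right hepatic lobe.",
    lambda rng: f"약 {rng.randint(1, 9)}.{rng.randint(1, 9)} cm 크기의 낭종이 관찰됨.",
]

FILLER_OTHER = [
    "Nerve conduction study 시행함.",
    "EEG shows normal background activity.",
    "근전도 검사상 이상 소견 없음.",
    "위 내시경 소견은 정상 범위임.",
    "보행 평가에서 경도의 개선이 관찰됨.",
    "연하 기능 평가 결과 정상임.",
    "Motor power is symmetric and intact.",
    "악력 측정값 28.5 kg으로 확인됨.",
    "보행 속도 0.9 m/s로 측정됨.",
]

_PARAM_FILLER_OTHER = [
    lambda rng: f"Latency {rng.randint(2, 6)}.{rng.randint(0, 9)} ms, amplitude {rng.randint(5, 20)}.{rng.randint(0, 9)} mV.",
    lambda rng: f"검사 장비 번호 {rng.randint(2100, 9899)}-{rng.randint(100, 999)} 사용함.",
    lambda rng: f"자극 강도 {rng.randint(10, 40)}.{rng.randint(0, 9)}, 주파수 {rng.randint(1, 9)}.{rng.randint(0, 9)} 기록됨.",
]

#: Non-PHI sentences the rule engine is known to false-positive on.
TRAP_LINES = [
    "이 lesion의 orientation을 고려해 볼 때 enlarged GB로 생각됨.",
    "측정치의 중앙값은 정상 범위임.",
    "Rt. 1st CMC joint에 mild OA 소견.",
    "상기확인함.",
]


# ---------------------------------------------------------------------------
# PHI rendering
# ---------------------------------------------------------------------------

def _pick_weighted(rng: random.Random, items: Sequence, weights: Sequence[float]):
    return rng.choices(list(items), weights=list(weights), k=1)[0]


def _date_surface(rng: random.Random) -> str:
    """Draw an in-scope date notation from a long-tailed mix.

    A few formats dominate (as in real notes) while many idiosyncratic
    per-physician notations sit in the tail — which is why the date rule
    family is the largest, and why small training corpora undersample the
    rare forms.
    """
    y = rng.randint(2012, 2023)
    m = rng.randint(1, 12)
    d = rng.randint(1, 28)
    yy = y % 100
    forms = [
        (20, lambda: f"{y}-{m:02d}-{d:02d}"),
        (20, lambda: f"{y}년 {m}월 {d}일"),
        (14, lambda: f"{y}.{m}.{d}"),
        (12, lambda: f"{m}월 {d}일"),
        (8, lambda: f"{y}/{m:02d}/{d:02d}"),
        (8, lambda: f"{y}년 {m}월"),
        (6, lambda: f"{y}. {m}. {d}"),
        (6, lambda: f"{y}{m:02d}{d:02d}"),
        (3, lambda: f"{y}년"),
        (3, lambda: f"'{yy:02d}.{m}.{d}"),
        (3, lambda: f"{MONTH_ABBR[m - 1]} {d}, {y}"),
        (3, lambda: f"{m}/{d}"),
        (1, lambda: f"{y}-{m:02d}-{d:02d} {rng.randint(8, 18)}:{rng.randint(0, 59):02d}"),
        (1, lambda: f"'{yy:02d}-{m}-{d}"),
        (1, lambda: f"{d} {MONTH_ABBR[m - 1]} {y}"),
        (1, lambda: f"{MONTH_FULL[m - 1]} {y}"),
    ]
    weights = [w for w, _ in forms]
    return _pick_weighted(rng, [f for _, f in forms], weights)()


def _date_surface_oos(rng: random.Random) -> Tuple[str, str]:
    # Out-of-scope date notations are lexical variants (partial dates,
    # relative months) rather than near-misses of covered numeric formats.
    m = rng.randint(1, 12)
    d = rng.randint(1, 28)
    month_lower = MONTH_FULL[m - 1].lower()
    choices = [
        (f"{m}월초", "{phi} 시행한 검사와 비교함."),
        (f"{m}월 말경", "{phi} 촬영 예정임."),
        (f"{m}월 중순", "{phi} 시행한 검사와 비교함."),
        (f"지난달 {d}일", "{phi} 촬영한 영상과 비교함."),
        (f"{d}일전", "{phi} 증상 발생함."),
        ("last November", "compared with the study of {phi}."),
        (f"early {month_lower}", "compared with the study of {phi}."),
    ]
    return rng.choice(choices)


_DAT_TEMPLATES = [
    "{phi} 촬영한 영상과 비교함.",
    "{phi} 시행한 검사 참조.",
    "comparison with prior study of {phi} was done.",
    "이전 검사 {phi} 참조.",
    "{phi} 추적 검사 권함.",
]

_STAFF_IN_SCOPE = [
    (8, lambda rng: ("판독의: {phi}", rng.choice(KOREAN_NAMES))),
    (5, lambda rng: ("판독의 {phi}", rng.choice(KOREAN_NAMES))),
    (5, lambda rng: ("추가 소견 {phi} 확인함.", rng.choice(KOREAN_NAMES))),
    (4, lambda rng: ("confirmed by {phi}.", rng.choice(KOREAN_NAMES))),
    (2, lambda rng: ("의료진 {phi} 소견 기재함.", rng.choice(KOREAN_NAMES))),
    (2, lambda rng: ("검사 by {phi} 시행됨.", rng.choice(KOREAN_NAMES))),
    (2, lambda rng: ("판독 완료 /{phi}/", rng.choice(INITIALS))),
    (1, lambda rng: ("{phi} 교수와 상의함.", rng.choice(KOREAN_NAMES))),
    (1, lambda rng: ("confirmed by {phi}.", rng.choice(ENGLISH_NAMES))),
    (1, lambda rng: ("외부 영상 from {phi} 전달받음.", rng.choice(KOREAN_NAMES))),
]

_STAFF_OUT_OF_SCOPE = [
    lambda rng: ("{phi} 선생님과 논의함.", rng.choice(KOREAN_NAMES)),
    lambda rng: ("discussed with {phi}.", rng.choice(KOREAN_NAMES)),
    lambda rng: ("서명: {phi}", rng.choice(KOREAN_NAMES)),
    lambda rng: ("re-read {phi} 판독 완료.", rng.choice(KOREAN_NAMES)),
    lambda rng: ("Dr. {phi} 소견 참조.", rng.choice(KOREAN_NAMES)),
    lambda rng: ("담당 {phi} 기재함.", rng.choice(KOREAN_NAMES)),
]

_PATIENT_IN_SCOPE = [
    lambda rng: ("환자이름: {phi}", rng.choice(KOREAN_NAMES)),
    lambda rng: ("환자이름 (patient name): {phi}", rng.choice(KOREAN_NAMES)),
    lambda rng: ("환자명: {phi}", rng.choice(KOREAN_NAMES)),
]

_PATIENT_OUT_OF_SCOPE = [
    lambda rng: ("내원한 {phi} 님의 검사임.", rng.choice(KOREAN_NAMES)),
    lambda rng: ("보호자 동행, 환자 {phi} 내원함.", rng.choice(KOREAN_NAMES)),
]

_ORG_TEMPLATES = [
    "{phi} 에서 시행한 검사와 비교함.",
    "{phi} 외부 영상 참조.",
    "{phi} 으로 전원 예정임.",
]

_LOC_TEMPLATES = [
    "{phi} 소재 의료기관에서 시행함.",
    "{phi} local 검사 영상임.",
]

_NUM_IN_SCOPE = [
    lambda rng: ("문의는 Tel. {phi} 로 연락 바람.", _ext_digits(rng)),
    lambda rng: ("문의는 T. {phi} 로 연락 바람.", _ext_digits(rng)),
    lambda rng: ("전화번호: {phi}", f"0{rng.randint(2, 6)}1-{rng.randint(300, 899)}-{rng.randint(1000, 9999)}"),
    lambda rng: ("환자번호: {phi}", str(rng.randint(30000000, 89999999))),
]

_NUM_OUT_OF_SCOPE = [
    lambda rng: ("내선 {phi} 로 문의 바람.", _ext_digits(rng)),
    lambda rng: ("연락처 {phi} 기재됨.", _ext_digits(rng)),
]


def _ext_digits(rng: random.Random) -> str:
    # First digit 3-8 so four-digit extensions never collide with years.
    return str(rng.randint(3000, 8999))


def _etc_surface(rng: random.Random, in_scope: bool) -> Tuple[str, str]:
    n = rng.randint(18, 95)
    if in_scope:
        choices = [
            (f"{n}세 {rng.choice(['남자', '여자'])}", "{phi} 환자의 검사임."),
            (f"{rng.choice(['M', 'F'])}/{n}", "{phi} 검사 소견임."),
            (f"{n}-year-old {rng.choice(['male', 'female'])}", "study of a {phi} patient."),
            (rng.choice(NATIONALITIES), "{phi} 환자로 의사소통에 유의 바람."),
        ]
    else:
        choices = [
            (f"{(n // 10) * 10}대 {rng.choice(['남', '여'])}", "{phi} 환자의 검사임."),
            ("elderly man", "study of an {phi} with prior history."),
        ]
    return rng.choice(choices)


def render_phi(
    category: PHICategory,
    in_scope: bool,
    rng: random.Random,
    subcategory: Optional[PersonRole] = None,
) -> Tuple[str, str]:
    """Draw a PHI surface and its context template (with a {phi} slot).

    ``in_scope=True`` draws from notation families the default rule set
    covers; ``in_scope=False`` from documented uncovered variants.
    """
    if category is PHICategory.DAT:
        if in_scope:
            return _date_surface(rng), rng.choice(_DAT_TEMPLATES)
        surface, template = _date_surface_oos(rng)
        return surface, template
    if category is PHICategory.PER:
        role = subcategory or PersonRole.STAFF
        if role is PersonRole.STAFF:
            if in_scope:
                builder = _pick_weighted(
                    rng, [b for _, b in _STAFF_IN_SCOPE], [w for w, _ in _STAFF_IN_SCOPE]
                )
            else:
                builder = rng.choice(_STAFF_OUT_OF_SCOPE)
        else:
            builder = rng.choice(_PATIENT_IN_SCOPE if in_scope else _PATIENT_OUT_OF_SCOPE)
        template, surface = builder(rng)
        return surface, template
    if category is PHICategory.ORG:
        if in_scope:
            surface = _pick_weighted(
                rng, [a for _, a in ORG_IN_SCOPE_WEIGHTED], [w for w, _ in ORG_IN_SCOPE_WEIGHTED]
            )
        else:
            surface = rng.choice(ORG_OUT_OF_SCOPE)
        return surface, rng.choice(_ORG_TEMPLATES)
    if category is PHICategory.LOC:
        surface = rng.choice(LOC_IN_SCOPE if in_scope else LOC_OUT_OF_SCOPE)
        return surface, rng.choice(_LOC_TEMPLATES)
    if category is PHICategory.NUM:
        pool = _NUM_IN_SCOPE if in_scope else _NUM_OUT_OF_SCOPE
        template, surface = rng.choice(pool)(rng)
        return surface, template
    if category is PHICategory.ETC:
        surface, template = _etc_surface(rng, in_scope)
        return surface, template
    raise DeidError(f"unknown category {category}")


def _weighted_choice(rng: random.Random, mix: Dict[str, float]) -> str:
    keys = sorted(mix)
    weights = [mix[k] for k in keys]
    return rng.choices(keys, weights=weights, k=1)[0]


def _filler_line(dept: Department, rng: random.Random) -> str:
    if dept is Department.OTHER:
        static, param = FILLER_OTHER, _PARAM_FILLER_OTHER
    else:
        static, param = FILLER_RADIOLOGY, _PARAM_FILLER_RADIOLOGY
    if rng.random() < 0.5:
        return rng.choice(param)(rng)
    return rng.choice(static)


def _generate_note(note_id: str, dept: Department, cfg: SynthConfig, rng: random.Random) -> AnnotatedNote:
    n_filler = rng.randint(2, 4)
    lines: List[Tuple[str, List[Tuple[int, int, PHICategory, Optional[PersonRole]]]]] = [
        (_filler_line(dept, rng), []) for _ in range(n_filler)
    ]

    if rng.random() < cfg.phi_note_fraction:
        # Notation style is an author property: a writer who uses uncovered
        # notation uses it throughout the note, so scope is drawn per note.
        in_scope = rng.random() >= cfg.out_of_scope_fraction
        k = 2 if rng.random() < cfg.second_instance_rate else 1
        for _ in range(k):
            key = _weighted_choice(rng, cfg.category_mix)
            category, role = _MIX_KEYS[key]
            surface, template = render_phi(category, in_scope, rng, subcategory=role)
            idx = template.index("{phi}")
            line = template.replace("{phi}", surface)
            rel = [(idx, idx + len(surface), category, role)]
            lines.insert(rng.randint(0, len(lines)), (line, rel))

    offset = 0
    parts: List[str] = []
    annotations: List[PHIAnnotation] = []
    for i, (line, rels) in enumerate(lines):
        if i:
            offset += 1  # newline
        for start, end, category, role in rels:
            annotations.append(
                PHIAnnotation(
                    span=Span(offset + start, offset + end),
                    category=category,
                    surface=line[start:end],
                    subcategory=role,
                )
            )
        parts.append(line)
        offset += len(line)
    note = ClinicalNote(note_id=note_id, department=dept, text="\n".join(parts))
    annotated = AnnotatedNote(note, sorted(annotations, key=lambda a: a.span.start))
    return inject_homonym_traps(annotated, cfg.homonym_trap_rate, rng)


def inject_homonym_traps(annotated: AnnotatedNote, rate: float, rng: random.Random) -> AnnotatedNote:
    """With probability ``rate``, append a known false-positive trap line.

    Traps are appended after all existing text, so gold spans are unchanged;
    the trap text itself is gold-O.
    """
    if not (0.0 <= rate <= 1.0):
        raise DeidError(f"trap rate must be in [0, 1], got {rate}")
    if rng.random() >= rate:
        return annotated
    trap = rng.choice(TRAP_LINES)
    note = ClinicalNote(
        note_id=annotated.note.note_id,
        department=annotated.note.department,
        text=annotated.note.text + "\n" + trap,
    )
    return AnnotatedNote(note, list(annotated.annotations))


def generate_corpus(config: SynthConfig) -> List[AnnotatedNote]:
    """Generate ``config.n_notes`` annotated notes, deterministically under
    ``config.seed``."""
    config.validate()
    rng = random.Random(config.seed)
    out: List[AnnotatedNote] = []
    for i in range(config.n_notes):
        dept = Department.OTHER if rng.random() < config.department_mix else Department.RADIOLOGY
        out.append(_generate_note(f"synth{config.seed}-{i:06d}", dept, config, rng))
    return out
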