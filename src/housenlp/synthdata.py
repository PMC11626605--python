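"""Template-based generator of labeled synthetic ED discharge notes.

The generator emulates a formulaic, shareable test corpus of
emergency-department discharge notes: every note has the same skeleton
(chief complaint, HPI, exam, assessment/plan, disposition, patient
education) and one injected housing scenario drawn from six classes:

* ``affirmed`` — the patient has a housing problem, stated plainly
  (gold label: positive);
* ``negated`` — a housing concept under a negation trigger (negative);
* ``absent`` — no housing language at all (negative);
* ``family_member`` — a relative, not the patient, has the problem
  (negative; correctly handled via the experiencer dimension);
* ``third_party`` — an unrelated person is described ("a homeless person
  sleeping in her bathroom"); negative gold, but *designed* to fool the
  pipeline — there is no contextual marker a rule can use;
* ``resource_list`` — a housing phrase inside a generic patient-education
  resource list ("Homeless Veterans Center"); negative gold, also
  adversarial by design.

Class counts come from largest-remainder apportionment of the requested
mix, so they are exact and deterministic; the seeded RNG only picks
templates and phrases. Every injection is recorded in a per-note ledger,
which is what the evaluation harness treats as annotation ground truth.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .lexicon import ConceptCategory
from .segmenter import ClinicalNote, segment

__all__ = [
    "CLASSES",
    "ADVERSARIAL_CLASSES",
    "GeneratorSpec",
    "Injection",
    "GeneratedNote",
    "generate_corpus",
    "corpus_to_files",
]

CLASSES = ("affirmed", "negated", "absent", "family_member", "third_party", "resource_list")
ADVERSARIAL_CLASSES = ("third_party", "resource_list")

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic corpus.

    Defaults reproduce the formulaic positive/negative test-cohort setup:
    200 notes, 40% affirmed / 30% negated / 30% absent, seed 42.
    """

    n_notes: int = 200
    class_mix: dict = field(
        default_factory=lambda: {"affirmed": 0.4, "negated": 0.3, "absent": 0.3}
    )
    concept_mix: dict = field(
        default_factory=lambda: {c: 1 / 6 for c in ConceptCategory}
    )
    seed: int = 42
    style: str = "formulaic"  # "formulaic" | "noisy"

    def validate(self) -> None:
        if self.n_notes <= 0:
            raise ValueError("n_notes must be positive")
        if self.style not in ("formulaic", "noisy"):
            raise ValueError(f"unknown style {self.style!r}")
        for name, mix, universe in (
            ("class_mix", self.class_mix, CLASSES),
            ("concept_mix", self.concept_mix, tuple(ConceptCategory)),
        ):
            unknown = set(mix) - set(universe)
            if unknown:
                raise ValueError(f"{name}: unknown keys {sorted(map(str, unknown))}")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"{name}: proportions must be non-negative")
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name}: proportions sum to {total}, not 1")

    def to_dict(self) -> dict:
        return {
            "n_notes": self.n_notes,
            "class_mix": dict(self.class_mix),
            "concept_mix": {str(k): v for k, v in self.concept_mix.items()},
            "seed": self.seed,
            "style": self.style,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorSpec":
        return cls(
            n_notes=d["n_notes"],
            class_mix=dict(d["class_mix"]),
            concept_mix={ConceptCategory(k): v for k, v in d["concept_mix"].items()},
            seed=d["seed"],
            style=d["style"],
        )


@dataclass(frozen=True)
class Injection:
    phrase: str
    concept: Optional[ConceptCategory]
    cls: str
    sentence_index: int


@dataclass(frozen=True)
class GeneratedNote:
    note: ClinicalNote
    gold_label: str
    ledger: tuple[Injection, ...]


def apportion(n: int, mix: dict, order: Sequence) -> dict:
    """Largest-remainder (Hamilton) apportionment of n among mix's keys.

    Ties in the fractional remainders break by position in *order*, so the
    result is exact and deterministic: counts sum to n and each count is
    within 1 of its quota.
    """
    keys = [k for k in order if mix.get(k, 0) > 0]
    quotas = {k: n * mix[k] for k in keys}
    counts = {k: int(quotas[k]) for k in keys}
    remaining = n - sum(counts.values())
    by_remainder = sorted(
        keys, key=lambda k: (-(quotas[k] - counts[k]), list(order).index(k))
    )
    for k in by_remainder[:remaining]:
        counts[k] += 1
    return counts


# ---------------------------------------------------------------------------
# Template pools. Injected housing sentences per concept and class. Every
# affirmed phrase is a surface form the shipped lexicon matches; negated and
# family sentences put the phrase inside the forward scope of a shipped
# negation or experiencer trigger in the same sentence.
# ---------------------------------------------------------------------------

_AFFIRMED: dict[ConceptCategory, list[tuple[str, str]]] = {
    ConceptCategory.HOMELESS: [
        ("homeless", "Patient reports being homeless for the past several months."),
        ("living on the streets", "Patient states that he has been living on the streets since losing employment."),
        ("homelessness", "Social work was consulted regarding ongoing homelessness."),
        ("unhoused", "Patient is currently unhoused and sleeps in the park."),
        ("homelesss", "Triage documentation describes the patient as homelesss."),
    ],
    ConceptCategory.UNSTABLE_HOUSING: [
        ("housing instability", "Patient describes significant housing instability over the past year."),
        ("unstable housing", "Patient reports unstable housing and frequent moves between apartments."),
        ("couch surfing", "Patient has been couch surfing at acquaintances' apartments."),
        ("facing eviction", "Patient is facing eviction at the end of the month."),
    ],
    ConceptCategory.RECOVERY_HOUSING: [
        ("sober living home", "Patient resides at a sober living home in town."),
        ("recovery housing", "Patient entered recovery housing two weeks ago."),
        ("halfway house", "Patient currently lives at a halfway house."),
    ],
    ConceptCategory.EMERGENCY_HOUSING: [
        ("emergency shelter", "Patient was referred to an emergency shelter for tonight."),
        ("homeless shelter", "Patient has been sleeping at the downtown homeless shelter."),
        ("warming center", "Patient spent the night at the warming center during the storm."),
    ],
    ConceptCategory.TEMPORARY_HOUSING: [
        ("staying in a shelter", "Patient is currently staying in a shelter with her children."),
        ("temporary housing", "Patient was placed in temporary housing by the county program."),
        ("transitional housing", "Patient moved into transitional housing after discharge from rehab."),
    ],
    ConceptCategory.EXPOSURE: [
        ("cold exposure", "Patient presented with cold exposure after spending the night outdoors."),
        ("exposure to the elements", "Exam findings are consistent with prolonged exposure to the elements."),
        ("heat exposure", "Patient was treated for heat exposure sustained while living outdoors."),
    ],
}

_NEGATED: dict[ConceptCategory, list[tuple[str, str]]] = {
    ConceptCategory.HOMELESS: [
        ("homeless", "Patient denies being homeless and reports a stable apartment."),
        ("homelessness", "Patient denies any homelessness now or in the past."),
        ("living on the streets", "Patient is not living on the streets and returns to his own apartment."),
    ],
    ConceptCategory.UNSTABLE_HOUSING: [
        ("housing instability", "Patient denies housing instability and has lived at the same address for years."),
        ("unstable housing", "There is no unstable housing situation reported by the patient."),
    ],
    ConceptCategory.RECOVERY_HOUSING: [
        ("recovery housing", "Patient is not in recovery housing at this time."),
        ("sober living", "Patient denies residing in sober living currently."),
    ],
    ConceptCategory.EMERGENCY_HOUSING: [
        ("emergency shelter", "No emergency shelter placement was required for this patient."),
        ("emergency housing", "Patient denied needing emergency housing assistance."),
    ],
    ConceptCategory.TEMPORARY_HOUSING: [
        ("staying in a shelter", "Patient is not staying in a shelter and lives with a stable lease."),
        ("temporary housing", "Patient denies living in temporary housing arrangements."),
    ],
    ConceptCategory.EXPOSURE: [
        ("cold exposure", "Patient denies any recent cold exposure."),
        ("exposure to the elements", "There was no exposure to the elements during the episode."),
    ],
}

_FAMILY: dict[ConceptCategory, list[tuple[str, str]]] = {
    ConceptCategory.HOMELESS: [
        ("homeless", "Patient reports that her brother is homeless and occasionally asks to stay with her."),
        ("homelessness", "Patient is worried because her mother is experiencing homelessness."),
    ],
    ConceptCategory.UNSTABLE_HOUSING: [
        ("housing instability", "Patient mentions that his sister struggles with housing instability."),
    ],
    ConceptCategory.RECOVERY_HOUSING: [
        ("recovery housing", "Patient shares that his brother recently entered recovery housing."),
    ],
    ConceptCategory.EMERGENCY_HOUSING: [
        ("emergency shelter", "Patient says her daughter slept at an emergency shelter last week."),
    ],
    ConceptCategory.TEMPORARY_HOUSING: [
        ("staying in a shelter", "Patient notes that his father has been staying in a shelter."),
    ],
    ConceptCategory.EXPOSURE: [
        ("cold exposure", "Patient reports her uncle was hospitalized for cold exposure last winter."),
    ],
}

_THIRD_PARTY_SENTENCES: list[tuple[str, ConceptCategory, str]] = [
    ("homeless", ConceptCategory.HOMELESS,
     "Patient presented to the emergency department after finding a homeless person sleeping in her bathroom."),
    ("homeless", ConceptCategory.HOMELESS,
     "Patient called 911 after an altercation with a homeless man outside the store."),
    ("unhoused", ConceptCategory.HOMELESS,
     "Patient witnessed an unhoused individual collapse at the bus stop and performed CPR."),
]

_RESOURCE_LINES: list[tuple[str, ConceptCategory, str]] = [
    ("Homeless", ConceptCategory.HOMELESS, "Homeless Veterans Center: 555-0142"),
    ("emergency shelter", ConceptCategory.EMERGENCY_HOUSING, "County emergency shelter hotline: 211"),
    ("transitional housing", ConceptCategory.TEMPORARY_HOUSING, "Transitional housing program intake line: 555-0188"),
]

# optional adversarial template, off by default: a phrasing pattern unlikely
# in real notes, retained only for stress-testing negation handling
_UNREALISTIC_NEGATED = (
    "homelessness",
    ConceptCategory.HOMELESS,
    "There were no visible signs of homelessness.",
)

_CHIEF_COMPLAINTS = [
    "Chest pain", "Abdominal pain", "Shortness of breath", "Laceration to left hand",
    "Ankle injury", "Headache", "Fever and cough", "Back pain", "Dizziness",
    "Nausea and vomiting",
]

_HPI_FILLER = [
    "The patient is a {age}-year-old {sex} presenting with {cc_lower}.",
    "Symptoms began approximately {hours} hours prior to arrival.",
    "The patient rates the discomfort {pain} out of 10.",
    "There is an associated mild {assoc}.",
    "The patient took {med} at home with partial relief.",
]

_EXAM_LINES = [
    "Vital signs are within normal limits.",
    "The patient is alert and oriented, in no acute distress.",
    "Cardiovascular exam reveals a regular rate and rhythm.",
    "Lungs are clear to auscultation bilaterally.",
    "Abdomen is soft and nontender.",
]

_PLAN_LINES = [
    "Laboratory studies and imaging were unremarkable.",
    "The patient was treated symptomatically in the department.",
    "Return precautions were discussed in detail.",
    "Follow up with primary care within one week.",
]

_EDUCATION_LINES = [
    "Take medications as directed.",
    "Rest and hydrate over the next several days.",
    "Return to the emergency department for worsening symptoms.",
]

_ASSOC = ["nausea", "fatigue", "photophobia", "sweating"]
_MEDS = ["acetaminophen", "ibuprofen", "antacids"]
_SEX = ["male", "female"]


def _pick(rng: random.Random, pool: Sequence):
    return pool[rng.randrange(len(pool))]


def _build_note(
    note_id: str, cls: str, concept: Optional[ConceptCategory], rng: random.Random, style: str
) -> GeneratedNote:
    cc = _pick(rng, _CHIEF_COMPLAINTS)
    hpi = [
        line.format(
            age=rng.randrange(19, 90),
            sex=_pick(rng, _SEX),
            cc_lower=cc.lower(),
            hours=rng.randrange(1, 48),
            pain=rng.randrange(2, 10),
            assoc=_pick(rng, _ASSOC),
            med=_pick(rng, _MEDS),
        )
        for line in _HPI_FILLER[: rng.randrange(3, len(_HPI_FILLER) + 1)]
    ]

    injected: list[tuple[str, Optional[ConceptCategory], str]] = []  # phrase, concept, sentence
    education = list(_EDUCATION_LINES)
    if cls == "affirmed":
        phrase, sentence = _pick(rng, _AFFIRMED[concept])
        hpi.append(sentence)
        injected.append((phrase, concept, sentence))
    elif cls == "negated":
        phrase, sentence = _pick(rng, _NEGATED[concept])
        hpi.append(sentence)
        injected.append((phrase, concept, sentence))
    elif cls == "family_member":
        phrase, sentence = _pick(rng, _FAMILY[concept])
        hpi.append(sentence)
        injected.append((phrase, concept, sentence))
    elif cls == "third_party":
        phrase, tp_concept, sentence = _pick(rng, _THIRD_PARTY_SENTENCES)
        hpi.insert(1, sentence)
        injected.append((phrase, tp_concept, sentence))
    elif cls == "resource_list":
        phrase, rl_concept, line = _pick(rng, _RESOURCE_LINES)
        education.append(line)
        injected.append((phrase, rl_concept, line))
    elif cls != "absent":
        raise ValueError(f"unknown class {cls!r}")

    if style == "noisy":
        # irregular spacing and casing, the kind real notes carry
        hpi = [line.replace(". ", ".  ") for line in hpi]
        cc = cc.upper()

    lines = [
        f"CHIEF COMPLAINT: {cc}",
        "",
        "HISTORY OF PRESENT ILLNESS:",
        *hpi,
        "",
        "PHYSICAL EXAM:",
        *_EXAM_LINES[: rng.randrange(3, len(_EXAM_LINES) + 1)],
        "",
        "ASSESSMENT AND PLAN:",
        *_PLAN_LINES[: rng.randrange(2, len(_PLAN_LINES) + 1)],
        "",
        "PATIENT EDUCATION:",
        *education,
        "",
        "DISPOSITION:",
        "Discharged home in stable condition.",
    ]
    text = "\n".join(lines) + "\n"

    note = ClinicalNote(note_id=note_id, text=text)
    sentences = segment(note)
    ledger: list[Injection] = []
    for phrase, inj_concept, sentence_text in injected:
        needle = sentence_text.strip()
        index = next(
            s.index for s in sentences if needle.startswith(s.text) or s.text == needle
        )
        ledger.append(
            Injection(phrase=phrase, concept=inj_concept, cls=cls, sentence_index=index)
        )
    gold = POSITIVE if any(i.cls == "affirmed" for i in ledger) else NEGATIVE
    return GeneratedNote(note=note, gold_label=gold, ledger=tuple(ledger))


def generate_corpus(spec: GeneratorSpec) -> list[GeneratedNote]:
    """Generate a deterministic corpus; same spec (incl. seed) → identical notes."""
    spec.validate()
    class_counts = apportion(spec.n_notes, spec.class_mix, CLASSES)
    # deterministic class sequence: canonical order, block per class
    schedule: list[str] = []
    for cls in CLASSES:
        schedule.extend([cls] * class_counts.get(cls, 0))
    rng = random.Random(spec.seed)
    # concepts apportioned within the classes that need one
    concept_classes = {"affirmed", "negated", "family_member"}
    n_conceptful = sum(1 for cls in schedule if cls in concept_classes)
    concept_counts = apportion(n_conceptful, spec.concept_mix, tuple(ConceptCategory))
    concept_sequence: list[ConceptCategory] = []
    for concept in ConceptCategory:
        concept_sequence.extend([concept] * concept_counts.get(concept, 0))
    width = max(4, len(str(spec.n_notes)))
    corpus: list[GeneratedNote] = []
    ci = 0
    for i, cls in enumerate(schedule):
        concept = None
        if cls in concept_classes:
            concept = concept_sequence[ci]
            ci += 1
        note_id = f"note_{i:0{width}d}"
        corpus.append(_build_note(note_id, cls, concept, rng, spec.style))
    return corpus


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def corpus_to_files(corpus: Sequence[GeneratedNote], outdir: str | Path,
                    spec: Optional[GeneratorSpec] = None) -> dict:
    """Write one .txt per note, gold.csv, ledger.jsonl, and a manifest.

    The manifest records the generating spec (including the seed) and a
    sha256 per file, so a re-run from the recorded spec can be verified
    byte-for-byte.
    """
    outdir = Path(outdir)
    notes_dir = outdir / "notes"
    notes_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for gn in corpus:
        p = notes_dir / f"{gn.note.note_id}.txt"
        p.write_text(gn.note.text, encoding="utf-8")
        files[str(p.relative_to(outdir))] = _sha256(p)
    gold_path = outdir / "gold.csv"
    with open(gold_path, "w", newline="", encoding="utf-8") as fh:
        fh.write("note_id,label\n")
        for gn in corpus:
            fh.write(f"{gn.note.note_id},{gn.gold_label}\n")
    files["gold.csv"] = _sha256(gold_path)
    ledger_path = outdir / "ledger.jsonl"
    with open(ledger_path, "w", encoding="utf-8") as fh:
        for gn in corpus:
            for inj in gn.ledger:
                fh.write(json.dumps({
                    "note_id": gn.note.note_id,
                    "phrase": inj.phrase,
                    "concept": str(inj.concept) if inj.concept else None,
                    "class": inj.cls,
                    "sentence_index": inj.sentence_index,
                }, sort_keys=True) + "\n")
    files["ledger.jsonl"] = _sha256(ledger_path)
    manifest = {
        "spec": spec.to_dict() if spec else None,
        "n_notes": len(corpus),
        "files": files,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
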