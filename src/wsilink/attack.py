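"""The linkage-attack model and the worst-case probe attack success rate.

The prosecutor-style threat model: an attacker holds background knowledge
``B`` — one patient-labelled slide per patient — and receives anonymous probe
slides ``P``.  An attack ``f`` maps every probe to a patient.  A patient is
*f-vulnerable* when at least one of their probes is assigned back to them,
and the worst-case probe attack success rate

    R_s(f) = (number of f-vulnerable patients) / |H|

is the fraction of the cohort the attack re-identifies.  A prior-weighted
variant sums patient weights over the vulnerable set instead of counting.

Two concrete attacks are provided: nearest-neighbour assignment in a feature
space (ties broken deterministically by the smallest background index) and
exact linkage by cryptographic hash for bit-identical data.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .features import (
    DEFAULT_EXTRACTOR,
    ExtractorSpec,
    FeatureVector,
    ImageThumb,
    extract_features,
    get_extractor_spec,
    preprocess_image,
    similarity_matrix,
)

__all__ = [
    "BackgroundItem",
    "PatientPriors",
    "RsResult",
    "NO_MATCH",
    "validate_ground_truth",
    "is_vulnerable",
    "compute_rs",
    "compute_weighted_rs",
    "assign_by_similarity",
    "exact_match_assign",
    "sha256_digest",
    "evaluate_attack",
    "evaluate_exact_match",
]

#: Distinguished result of exact-match linkage when no background digest matches.
NO_MATCH = None

# Ground truth G: patient -> set of probe ids (possibly empty).
GroundTruth = Mapping[str, Set[str]]
# Attack f: probe id -> patient id.  May be partial for attacks that abstain
# (exact matching); an unassigned probe can never make a patient vulnerable.
Assignment = Mapping[str, str]


@dataclass(frozen=True)
class BackgroundItem:
    """One background-knowledge slide: the patient it is labelled with and the
    slide (item) identifier.  List position is the tie-breaking order."""

    patient_id: str
    item_id: str


@dataclass(frozen=True)
class RsResult:
    rs: float
    n_vulnerable: int
    n_patients: int
    vulnerable_ids: frozenset

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (0 <= self.n_vulnerable <= self.n_patients):
            raise ValueError("n_vulnerable must lie in [0, n_patients]")


def validate_ground_truth(truth: GroundTruth) -> None:
    """Probe sets of distinct patients must be disjoint."""
    seen: Dict[str, str] = {}
    for patient, probes in truth.items():
        for p in probes:
            if p in seen and seen[p] != patient:
                raise ValueError(
                    f"probe {p!r} claimed by both {seen[p]!r} and {patient!r}"
                )
            seen[p] = patient


def is_vulnerable(patient: str, assignment: Assignment, truth: GroundTruth) -> bool:
    """True iff some probe of ``patient`` is assigned back to ``patient``."""
    if patient not in truth:
        raise KeyError(f"patient {patient!r} missing from ground truth")
    return any(assignment.get(p) == patient for p in truth[patient])


def compute_rs(
    assignment: Assignment,
    truth: GroundTruth,
    patients: Iterable[str],
    *,
    exclude_probeless: bool = False,
) -> RsResult:
    """Worst-case probe attack success rate over ``patients``.

    Patients with an empty probe set count in the denominator by default
    (they can never be vulnerable); ``exclude_probeless=True`` drops them
    from both numerator and denominator for sensitivity analysis.
    """
    pts = list(patients)
    if not pts:
        raise ValueError("cannot compute R_s over an empty patient set")
    if exclude_probeless:
        pts = [h for h in pts if truth.get(h)]
        if not pts:
            raise ValueError("all patients are probeless; R_s undefined with exclude_probeless")
    vulnerable = frozenset(h for h in pts if is_vulnerable(h, assignment, truth))
    return RsResult(
        rs=len(vulnerable) / len(pts),
        n_vulnerable=len(vulnerable),
        n_patients=len(pts),
        vulnerable_ids=vulnerable,
    )


def compute_weighted_rs(
    assignment: Assignment,
    truth: GroundTruth,
    priors: Mapping[str, float],
    *,
    tol: float = 1e-9,
) -> float:
    """Prior-weighted success rate: the summed weight of vulnerable patients.

    With uniform priors 1/|H| this reduces to the unweighted rate.  Priors
    express attacker-side knowledge such as a matching source hospital.
    """
    total = float(sum(priors.values()))
    if abs(total - 1.0) > tol:
        raise ValueError(f"patient priors must sum to 1 (got {total!r})")
    if any(w < 0 or w > 1 for w in priors.values()):
        raise ValueError("patient priors must lie in [0, 1]")
    return float(
        sum(w for h, w in priors.items() if is_vulnerable(h, assignment, truth))
    )


def assign_by_similarity(
    probe_vec: FeatureVector,
    background: Sequence[BackgroundItem],
    background_vecs: Sequence[FeatureVector],
    measure: Callable | str = "cosine",
) -> str:
    """Assign a probe to the patient of the most similar background slide.

    The argmax over background items; when several items attain the maximum
    (exact float equality), the smallest list index wins, making the attack
    deterministic.
    """
    if len(background) == 0:
        raise ValueError("background knowledge is empty")
    if len(background) != len(background_vecs):
        raise ValueError("background and background_vecs lengths differ")
    if isinstance(measure, str):
        sims = similarity_matrix([probe_vec], background_vecs, measure)[0]
    else:
        sims = np.array([measure(probe_vec, b) for b in background_vecs])
    # np.argmax returns the first maximal index == smallest-index tie-break.
    return background[int(np.argmax(sims))].patient_id


def sha256_digest(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def exact_match_assign(
    probe_bytes: bytes,
    background_hashes: Sequence[Tuple[str, str]],
) -> Optional[str]:
    """Link a probe to a patient by exact SHA-256 digest equality.

    Returns the unique matching patient, or :data:`NO_MATCH` when no
    background digest equals the probe digest.  Bit-identical slides under
    two different patients indicate corrupt background data and raise.
    """
    by_digest: Dict[str, str] = {}
    for patient, digest in background_hashes:
        if digest in by_digest and by_digest[digest] != patient:
            raise ValueError(
                f"digest collision: {by_digest[digest]!r} and {patient!r} share {digest[:12]}…"
            )
        by_digest[digest] = patient
    return by_digest.get(sha256_digest(probe_bytes), NO_MATCH)


# ---------------------------------------------------------------------------
# End-to-end evaluation on a background/probe split
# ---------------------------------------------------------------------------

def _get_image(images, slide_id: str) -> ImageThumb:
    try:
        return images(slide_id) if callable(images) else images[slide_id]
    except KeyError:
        raise KeyError(f"no image available for slide {slide_id!r}") from None


def evaluate_attack(
    split,
    images,
    extractor: ExtractorSpec | str = DEFAULT_EXTRACTOR,
    measure: str = "cosine",
    *,
    preprocess_mode: str = "downscale",
    feature_cache: Optional[Dict] = None,
    exclude_probeless: bool = False,
) -> RsResult:
    """Run the similarity attack on one background/probe split.

    Features are extracted once per slide (optionally memoised across repeats
    in ``feature_cache``, keyed by slide id, extractor and preprocessing);
    every probe is assigned by nearest-neighbour similarity and R_s is
    computed over all patients of the split.

    ``split`` provides ``background`` (ordered :class:`BackgroundItem` list),
    ``truth`` and ``probe_ids``; ``images`` maps slide ids to
    :class:`ImageThumb` (mapping or callable).
    """
    spec = get_extractor_spec(extractor) if isinstance(extractor, str) else extractor

    def features_of(slide_id: str) -> FeatureVector:
        key = (slide_id, spec.name, preprocess_mode)
        if feature_cache is not None and key in feature_cache:
            return feature_cache[key]
        img = preprocess_image(_get_image(images, slide_id), preprocess_mode, spec.input_side)
        vec = extract_features(img, spec)
        if feature_cache is not None:
            feature_cache[key] = vec
        return vec

    background_vecs = [features_of(item.item_id) for item in split.background]
    assignment = {
        p: assign_by_similarity(features_of(p), split.background, background_vecs, measure)
        for p in split.probe_ids
    }
    patients = [item.patient_id for item in split.background]
    return compute_rs(assignment, split.truth, patients, exclude_probeless=exclude_probeless)


def evaluate_exact_match(split, images, *, exclude_probeless: bool = False) -> RsResult:
    """Run the bit-identical linkage attack (SHA-256 over raw pixel bytes)."""
    background_hashes = [
        (item.patient_id, sha256_digest(_get_image(images, item.item_id).pixels.tobytes()))
        for item in split.background
    ]
    assignment = {}
    for p in split.probe_ids:
        hit = exact_match_assign(_get_image(images, p).pixels.tobytes(), background_hashes)
        if hit is not NO_MATCH:
            assignment[p] = hit
    patients = [item.patient_id for item in split.background]
    return compute_rs(assignment, split.truth, patients, exclude_probeless=exclude_probeless)
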