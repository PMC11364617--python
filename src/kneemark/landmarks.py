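"""Landmark taxonomy for patellofemoral imaging protocols.

Thirteen anatomical landmarks are annotated across three 2-D acquisition
protocols:

* ``trochlear_sulcus`` (axial, trochlea fully exposed): T1/T2 posterior
  aspects of the lateral/medial femoral condyles, T3/T5 anterior aspects of
  the lateral/medial trochlear facets, T4 deepest point of the sulcus.
* ``proximal_trochlea`` (axial, first slice showing trochlear cartilage):
  T6/T7 lateral and medial margins of the lateral trochlear facet.
* ``patellar_height`` (sagittal, longest patellar axis): P1 proximal patellar
  pole, P2 distal end of the patellar articular surface, P3 proximal margin
  of the trochlear cartilage, P4 patellar apex, P5 patellar tendon insertion
  on the tibial tuberosity, P6 anterior aspect of the tibial plateau.
"""

from __future__ import annotations

from dataclasses import dataclass

TROCHLEAR_SULCUS = "trochlear_sulcus"
PROXIMAL_TROCHLEA = "proximal_trochlea"
PATELLAR_HEIGHT = "patellar_height"

PROTOCOLS = (TROCHLEAR_SULCUS, PROXIMAL_TROCHLEA, PATELLAR_HEIGHT)

_DESCRIPTIONS = {
    "T1": "posterior aspect of the lateral femoral condyle",
    "T2": "posterior aspect of the medial femoral condyle",
    "T3": "anterior aspect of the lateral trochlear facet",
    "T4": "deepest point of the trochlear sulcus",
    "T5": "anterior aspect of the medial trochlear facet",
    "T6": "lateral margin of the lateral trochlear facet",
    "T7": "medial margin of the lateral trochlear facet",
    "P1": "most proximal aspect of the patella",
    "P2": "most distal aspect of the patellar articular surface",
    "P3": "most proximal margin of the trochlear cartilage",
    "P4": "patella apex",
    "P5": "insertion of the patellar tendon on the tibial tuberosity",
    "P6": "anterior aspect of the tibia plateau",
}

PROTOCOL_LANDMARKS: dict[str, tuple[str, ...]] = {
    TROCHLEAR_SULCUS: ("T1", "T2", "T3", "T4", "T5"),
    PROXIMAL_TROCHLEA: ("T6", "T7"),
    PATELLAR_HEIGHT: ("P1", "P2", "P3", "P4", "P5", "P6"),
}


@dataclass(frozen=True)
class LandmarkDef:
    """Definition of one named landmark: its label, protocol and meaning."""

    label: str
    protocol: str
    description: str


LANDMARK_DEFS: dict[str, LandmarkDef] = {
    label: LandmarkDef(label, protocol, _DESCRIPTIONS[label])
    for protocol, labels in PROTOCOL_LANDMARKS.items()
    for label in labels
}


def landmarks_for(protocol: str) -> tuple[str, ...]:
    """Return the ordered landmark labels of ``protocol``."""
    try:
        return PROTOCOL_LANDMARKS[protocol]
    except KeyError:
        raise ValueError(
            f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}"
        ) from None


def validate_labels(labels, protocol: str) -> None:
    """Raise ``ValueError`` if any label does not belong to ``protocol``."""
    allowed = set(landmarks_for(protocol))
    bad = sorted(set(labels) - allowed)
    if bad:
        raise ValueError(
            f"labels {bad} are not valid for protocol {protocol!r}; "
            f"allowed: {sorted(allowed)}"
        )
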