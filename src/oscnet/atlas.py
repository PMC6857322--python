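"""The 112-region cortical + subcortical parcellation used for network nodes.

Nodes follow the Harvard-Oxford probabilistic anatomical parcellation
(48 cortical structures and 7 deep grey-matter structures per hemisphere,
plus left/right brainstem), yielding 112 regions of interest.  Labels are
ordered left/right interleaved, cortex first.  On-disk label files use
1-based indices; all in-memory arrays are 0-based.
"""

from __future__ import annotations

__all__ = ["atlas_labels", "index_of", "N_NODES"]

N_NODES = 112

_CORTICAL = [
    "Frontal Pole",
    "Insular Cortex",
    "Superior Frontal Gyrus",
    "Middle Frontal Gyrus",
    "Inferior Frontal Gyrus, pars triangularis",
    "Inferior Frontal Gyrus, pars opercularis",
    "Precentral Gyrus",
    "Temporal Pole",
    "Superior Temporal Gyrus, anterior division",
    "Superior Temporal Gyrus, posterior division",
    "Middle Temporal Gyrus, anterior division",
    "Middle Temporal Gyrus, posterior division",
    "Middle Temporal Gyrus, temporooccipital part",
    "Inferior Temporal Gyrus, anterior division",
    "Inferior Temporal Gyrus, posterior division",
    "Inferior Temporal Gyrus, temporooccipital part",
    "Postcentral Gyrus",
    "Superior Parietal Lobule",
    "Supramarginal Gyrus, anterior division",
    "Supramarginal Gyrus, posterior division",
    "Angular Gyrus",
    "Lateral Occipital Cortex, superior division",
    "Lateral Occipital Cortex, inferior division",
    "Intracalcarine Cortex",
    "Frontal Medial Cortex",
    "Juxtapositional Lobule Cortex",
    "Subcallosal Cortex",
    "Paracingulate Gyrus",
    "Cingulate Gyrus, anterior division",
    "Cingulate Gyrus, posterior division",
    "Precuneous Cortex",
    "Cuneal Cortex",
    "Frontal Orbital Cortex",
    "Parahippocampal Gyrus, anterior division",
    "Parahippocampal Gyrus, posterior division",
    "Lingual Gyrus",
    "Temporal Fusiform Cortex, anterior division",
    "Temporal Fusiform Cortex, posterior division",
    "Temporal Occipital Fusiform Cortex",
    "Occipital Fusiform Gyrus",
    "Frontal Operculum Cortex",
    "Central Opercular Cortex",
    "Parietal Operculum Cortex",
    "Planum Polare",
    "Heschl's Gyrus",
    "Planum Temporale",
    "Supracalcarine Cortex",
    "Occipital Pole",
]

_SUBCORTICAL = [
    "Thalamus",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Hippocampus",
    "Amygdala",
    "Accumbens",
]


def atlas_labels() -> list[str]:
    """Return the 112 node labels, left/right interleaved."""
    labels: list[str] = []
    for name in _CORTICAL + _SUBCORTICAL + ["Brain-Stem"]:
        labels.append(f"{name} L")
        labels.append(f"{name} R")
    assert len(labels) == N_NODES
    return labels


def index_of(name: str, hemisphere: str = "L") -> int:
    """0-based node index of a region, e.g. ``index_of("Putamen", "R")``."""
    label = f"{name} {hemisphere.upper()}"
    labels = atlas_labels()
    try:
        return labels.index(label)
    except ValueError:
        raise KeyError(f"region {label!r} not in the 112-node atlas") from None
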