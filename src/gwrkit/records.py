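"""Per-subject data container shared by the phantom generator, the sampler
and the group statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import VolumeGrid
from .mesh import TriangleMesh, VertexMap

__all__ = ["SubjectRecord"]


@dataclass
class SubjectRecord:
    """One subject: identity, group, covariates, and its data.

    ``maps`` collects per-vertex measures as they are computed
    (``gm_intensity``, ``wm_intensity``, ``gwr``, ``thickness``, smoothed
    variants ...).  ``volume`` and the surfaces may be dropped (set to None)
    once sampling is done to free memory.
    """

    subject_id: str
    group: str  # 'patient' | 'control'
    covariates: dict[str, float] = field(default_factory=dict)
    volume: VolumeGrid | None = None
    white: TriangleMesh | None = None
    pial: TriangleMesh | None = None
    maps: dict[str, VertexMap] = field(default_factory=dict)
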