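"""Spillover parsing, compensation, and automatic matrix selection.

Fluorescence detected in unintended channels is modelled linearly:
``observed = true @ S`` where S is the spillover matrix (rows = true
signal, columns = detectors, unit diagonal — the FCS $SPILLOVER
convention).  Compensation right-multiplies the detector sub-columns by
S^-1 and leaves every other channel untouched.

Matrix selection mirrors platform behaviour: a custom matrix stored in
the workspace for a sample takes precedence over the acquisition-time
$SPILLOVER keyword in the FCS file, which in turn takes precedence over
no compensation.  The selection is made automatically at import — it is
not a user knob, because changing it would move events across gate
boundaries and break faithful reproduction of the source analysis.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import (
    MalformedSpilloverError,
    SingularMatrixError,
    UnresolvedChannelError,
    UnresolvedCompensationError,
)
from .model import Sample, SpilloverMatrix, Workspace, UNCOMPENSATED

log = logging.getLogger(__name__)

SPILLOVER_KEYWORDS = ("$SPILLOVER", "$SPILL", "SPILL", "SPILLOVER")


def parse_spillover_keyword(text: str, matrix_id: str = "FCS") -> SpilloverMatrix:
    """Parse the FCS $SPILLOVER/$SPILL value "k,det1..detk,v11..vkk".

    The k*k coefficients are row-major; a matrix stored with a non-unit
    diagonal is normalized by scaling each row by its diagonal entry.
    """
    tokens = [t.strip() for t in text.split(",")]
    try:
        k = int(tokens[0])
    except (ValueError, IndexError):
        raise MalformedSpilloverError(
            f"spillover keyword does not start with a detector count: {text[:40]!r}")
    if k < 1 or len(tokens) != 1 + k + k * k:
        raise MalformedSpilloverError(
            f"spillover keyword has {len(tokens)} tokens, expected "
            f"{1 + k + k * k} for k={k}")
    detectors = tokens[1:1 + k]
    try:
        values = np.array([float(t) for t in tokens[1 + k:]], dtype=float)
    except ValueError as e:
        raise MalformedSpilloverError(f"non-numeric spillover coefficient: {e}")
    S = values.reshape(k, k)
    diag = np.diag(S).copy()
    if np.any(diag == 0):
        raise MalformedSpilloverError("spillover matrix has a zero diagonal entry")
    if not np.allclose(diag, 1.0):
        S = S / diag[:, None]
        log.info("spillover diagonal normalized by row-scaling")
    return SpilloverMatrix(detectors=detectors, S=S, matrix_id=matrix_id)


def compensate(events: np.ndarray, spill: SpilloverMatrix,
               channel_names: list[str]) -> np.ndarray:
    """Solve X = Y @ S^-1 on the detector columns; other columns unchanged."""
    idx = []
    for det in spill.detectors:
        if det not in channel_names:
            raise UnresolvedChannelError(
                f"spillover detector {det!r} not among sample channels")
        idx.append(channel_names.index(det))
    S = np.asarray(spill.S, dtype=float)
    if not np.all(np.isfinite(S)) or np.linalg.cond(S) > 1e12:
        raise SingularMatrixError(
            f"spillover matrix {spill.matrix_id!r} is singular or near-singular")
    out = np.array(events, dtype=float, copy=True)
    # X = Y S^-1  <=>  S' X' = Y'
    out[:, idx] = np.linalg.solve(S.T, events[:, idx].astype(float).T).T
    return out


def fcs_spillover(sample: Sample) -> SpilloverMatrix | None:
    """Spillover matrix parsed from the sample's FCS keywords, if any."""
    for kw in SPILLOVER_KEYWORDS:
        if kw in sample.keywords:
            return parse_spillover_keyword(sample.keywords[kw],
                                           matrix_id=f"FCS:{sample.sample_id}")
    return None


def select_compensation(sample: Sample, ws: Workspace,
                        gate_ref: str = UNCOMPENSATED) -> SpilloverMatrix | None:
    """Choose the spillover matrix for one sample/gate context.

    Precedence: an explicit matrix id on the gate dimension wins; otherwise
    a custom per-sample matrix registered in the workspace (the platform's
    analysis-time override) is detected and selected automatically; otherwise
    the acquisition-time FCS $SPILLOVER/$SPILL keyword; otherwise None
    (identity — no compensation).
    """
    if gate_ref != UNCOMPENSATED:
        if gate_ref not in ws.compensations:
            raise UnresolvedCompensationError(
                f"compensation_ref {gate_ref!r} not in workspace registry")
        log.info("compensation for %s: explicit gate reference %r",
                 sample.sample_id, gate_ref)
        return ws.compensations[gate_ref]
    custom_id = ws.sample_compensation.get(sample.sample_id)
    if custom_id is not None:
        if custom_id not in ws.compensations:
            raise UnresolvedCompensationError(
                f"per-sample compensation {custom_id!r} not in registry")
        log.info("compensation for %s: workspace custom matrix %r",
                 sample.sample_id, custom_id)
        return ws.compensations[custom_id]
    fcs = fcs_spillover(sample)
    if fcs is not None:
        log.info("compensation for %s: FCS $SPILLOVER keyword", sample.sample_id)
        return fcs
    log.info("compensation for %s: none (identity)", sample.sample_id)
    return None


def identity_spillover(detectors: list[str], matrix_id: str = "identity") -> SpilloverMatrix:
    return SpilloverMatrix(detectors=list(detectors),
                           S=np.eye(len(detectors)), matrix_id=matrix_id)


def spillover_to_keyword(spill: SpilloverMatrix) -> str:
    """Serialize to the FCS $SPILLOVER text form."""
    parts = [str(spill.k)] + list(spill.detectors)
    parts += [repr(float(v)) for v in np.asarray(spill.S).ravel()]
    return ",".join(parts)
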