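"""Tilt/twist angle tables from fitted coordinate models.

Drives the frame-fitting machinery over a declarative run configuration:
for each structure, an actin filament axis (pointed end of actin along
+z) and one or more troponin domain frames (the D-helix for the TnC
N-lobe, the TnI/TnT coiled-coil for the IT arm) are fitted, and the
(beta, gamma) orientation of each domain is tabulated.

The zero of gamma is a convention the angle definition leaves open; only
its sense (counterclockwise viewed from the C-terminal end of the
reference axis) is fixed. A single global gamma offset per domain type is
therefore calibrated once against one designated reference entry and then
frozen; every other tabulated entry is a prediction.

Configuration format (INI, one file per run)::

    [structure:NAME]
    path = model.pdb              ; or accession = 6KN7 (fetched+cached)
    state = APO                   ; free-text state label
    filament_chains = A,B,C,D,E   ; actin subunits, order along the axis
    pointed_end_chain = E         ; subunit nearest the pointed end

    [domain:NAME/IT_arm]
    kind = coiled_coil
    helix1 = I:90-135             ; chain:first-last, CA range
    helix2 = T:226-270
    ref_helix = C:95-102          ; gamma=0 witness (e.g. TnC E-helix)
    gamma_offset = 0.0

    [domain:NAME/TnC_N]
    kind = helix
    helix1 = C:74-88              ; D-helix
    ref_helix = C:15-22           ; A-helix
    gamma_offset = 0.0

Residue ranges are config data (annotation-derived defaults, overridable
per run); they are deliberately not inferred from the coordinates.
"""

from __future__ import annotations

import configparser
import dataclasses

import numpy as np
import pandas as pd

from .errors import FisskitError
from .frames import (
    AxisFrame,
    DomainOrientation,
    domain_orientation,
    fit_coiled_coil_axis,
    fit_filament_axis,
    fit_helix_axis,
    wrap_angle,
)
from .structio import AtomSelection, StructureModel, read_structure

__all__ = [
    "DomainSpec",
    "StructureJob",
    "parse_run_config",
    "compute_orientation",
    "angle_table",
    "calibrate_gamma_offset",
]


def _parse_sel(text: str, atom: str = "CA") -> AtomSelection:
    chain, rng = text.strip().split(":")
    first, last = rng.split("-")
    return AtomSelection(chain=chain, first=int(first), last=int(last), atom=atom)


@dataclasses.dataclass
class DomainSpec:
    name: str
    kind: str  # "helix" or "coiled_coil"
    helix1: AtomSelection
    helix2: AtomSelection | None = None
    ref_helix: AtomSelection | None = None
    gamma_offset: float = 0.0

    def fit_frame(self, model: StructureModel) -> AxisFrame:
        if self.kind == "helix":
            frame = fit_helix_axis(model, self.helix1)
        elif self.kind == "coiled_coil":
            if self.helix2 is None:
                raise FisskitError(f"domain {self.name}: coiled_coil needs helix2")
            frame = fit_coiled_coil_axis(model, self.helix1, self.helix2)
        else:
            raise FisskitError(f"domain {self.name}: unknown kind {self.kind!r}")
        if self.ref_helix is not None:
            ref_origin = fit_helix_axis(model, self.ref_helix).origin
            frame = AxisFrame(frame.origin, frame.axis, ref_origin - frame.origin)
        return frame


@dataclasses.dataclass
class StructureJob:
    name: str
    path: str | None
    accession: str | None
    state: str
    filament_chains: list
    pointed_end_chain: str | None
    domains: list  # DomainSpec

    def load(self) -> StructureModel:
        if self.path:
            return read_structure(self.path)
        if self.accession:
            from .fetch import fetch_structure

            return read_structure(fetch_structure(self.accession))
        raise FisskitError(f"structure {self.name}: neither path nor accession")


def parse_run_config(path) -> list:
    cfg = configparser.ConfigParser()
    read = cfg.read(path)
    if not read:
        raise FisskitError(f"cannot read run config {path}")
    jobs: dict[str, StructureJob] = {}
    for section in cfg.sections():
        if not section.startswith("structure:"):
            continue
        name = section.split(":", 1)[1]
        s = cfg[section]
        jobs[name] = StructureJob(
            name=name,
            path=s.get("path"),
            accession=s.get("accession"),
            state=s.get("state", ""),
            filament_chains=[c.strip() for c in s.get("filament_chains", "").split(",") if c.strip()],
            pointed_end_chain=s.get("pointed_end_chain"),
            domains=[],
        )
    for section in cfg.sections():
        if not section.startswith("domain:"):
            continue
        sname, dname = section.split(":", 1)[1].split("/", 1)
        if sname not in jobs:
            raise FisskitError(f"domain section {section} references unknown structure")
        s = cfg[section]
        jobs[sname].domains.append(
            DomainSpec(
                name=dname,
                kind=s.get("kind", "helix"),
                helix1=_parse_sel(s["helix1"]),
                helix2=_parse_sel(s["helix2"]) if "helix2" in s else None,
                ref_helix=_parse_sel(s["ref_helix"]) if "ref_helix" in s else None,
                gamma_offset=s.getfloat("gamma_offset", 0.0),
            )
        )
    if not jobs:
        raise FisskitError(f"run config {path} defines no structures")
    return list(jobs.values())


def compute_orientation(
    model: StructureModel, domain: DomainSpec, filament: AxisFrame
) -> DomainOrientation:
    """(beta, gamma) of one domain against a fitted filament frame.

    The filament frame's gamma=0 direction is the radial vector toward the
    domain origin; the configured per-domain-type offset is then applied.
    """
    dframe = domain.fit_frame(model)
    fil = filament.with_ref_toward(dframe.origin)
    o = domain_orientation(dframe, fil)
    return DomainOrientation(
        o.beta, wrap_angle(o.gamma + domain.gamma_offset), o.degenerate
    )


def angle_table(jobs) -> pd.DataFrame:
    """One row per (structure, domain); per-row errors recorded, run continues."""
    rows = []
    for job in jobs:
        try:
            model = job.load()
            filament = fit_filament_axis(
                model, job.filament_chains, job.pointed_end_chain
            )
        except Exception as exc:  # per-row error entry, keep going
            for dom in job.domains or [None]:
                rows.append(
                    {
                        "source_id": job.name,
                        "domain": dom.name if dom else "",
                        "state": job.state,
                        "beta_deg": np.nan,
                        "gamma_deg": np.nan,
                        "error": str(exc),
                    }
                )
            continue
        for dom in job.domains:
            try:
                o = compute_orientation(model, dom, filament)
                rows.append(
                    {
                        "source_id": job.name,
                        "domain": dom.name,
                        "state": job.state,
                        "beta_deg": round(o.beta, 2),
                        "gamma_deg": round(o.gamma, 2),
                        "error": "",
                    }
                )
            except Exception as exc:
                rows.append(
                    {
                        "source_id": job.name,
                        "domain": dom.name,
                        "state": job.state,
                        "beta_deg": np.nan,
                        "gamma_deg": np.nan,
                        "error": str(exc),
                    }
                )
    return pd.DataFrame(rows)


def calibrate_gamma_offset(computed_gamma: float, reference_gamma: float) -> float:
    """Offset that maps a computed gamma onto a designated reference entry.

    Applied globally per domain type and then frozen; all other entries
    become predictions.
    """
    return wrap_angle(reference_gamma - computed_gamma)
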