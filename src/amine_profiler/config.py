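"""Survey configuration: every geometric threshold in one place.

Defaults are the published criteria: 4.1 A acceptor prescreen around the
amine N, H-bond acceptance at <=2.5 A and >=140 deg, SASA probe 1.40 A,
ROI radii 7.5/12.5 A. Outputs embed a hash of the configuration actually
used.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .hbonds import HBondCriteria


@dataclass
class SurveyConfig:
    prescreen_radius: float = 4.1
    max_h_acceptor_distance: float = 2.5
    min_nha_angle: float = 140.0
    nh_bond_length: float = 1.01
    hnh_angle: float = 120.0
    probe_radius: float = 1.40
    sasa_points: int = 100
    roi1_radius: float = 7.5
    roi2_radius: float = 12.5
    exclude_parent_residue: bool = False
    sidechain_acceptors: bool = True
    model_policy: str | int = "first"
    altloc_policy: str = "occupancy"
    histogram_d_bin: float = 0.05
    histogram_a_bin: float = 2.0
    cluster_linkage: str = "average"
    cluster_grid_step: float = 0.05
    extra: dict = field(default_factory=dict)

    def criteria(self) -> HBondCriteria:
        return HBondCriteria(
            prescreen_radius=self.prescreen_radius,
            max_h_acceptor_distance=self.max_h_acceptor_distance,
            min_nha_angle=self.min_nha_angle,
            nh_bond_length=self.nh_bond_length,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "SurveyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        extra = {k: v for k, v in data.items() if k not in known}
        if extra:
            kwargs.setdefault("extra", {}).update(extra)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
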