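"""Model/Results presentation layer.

`SpineFEModel` is built from data (a CT volume and its label mask, or a
synthetic subject) and `fit()` runs the whole pipeline - densitometry,
meshing, material mapping, compression to failure, pure-moment ROM -
returning a `SpineFEResults` object that carries the estimates and
diagnostics and prints a summary table.  `CohortComparison` plays the same
role at the cohort level (descriptives, Spearman/Pearson correlations with
BMD, exact Mann-Whitney tests).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .ct import CTVolume, LabelMask
from .errors import SpineFEError
from .geometry import SpineGeometry
from .simulate import (
    SubjectRecord,
    geometry_from_mask,
    run_subject,
    synthesize_subject,
)
from . import io as sio
from . import stats as sstats


class SpineFEModel:
    """Patient-specific FE model of the whole lumbar spine (L1-L5).

    Parameters
    ----------
    volume, mask : CTVolume, LabelMask
        Calibrated CT data with per-structure labels (vertebrae, disc
        compartments, phantom inserts).
    config : RunConfig, optional
        Pipeline tunables; defaults reproduce the package's reference
        desk-scale study conditions.
    geometry : SpineGeometry, optional
        Known parametric geometry; reconstructed from the mask when absent.

    Examples
    --------
    >>> model = SpineFEModel.from_synthetic(target_bmd=100.0, seed=1)
    >>> res = model.fit()
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(
        self,
        volume: CTVolume,
        mask: LabelMask,
        config: RunConfig | None = None,
        geometry: SpineGeometry | None = None,
        subject_id: str = "subject",
    ):
        self.volume = volume
        self.mask = mask
        self.config = config or RunConfig()
        self._geometry = geometry
        self.subject_id = subject_id

    @property
    def geometry(self) -> SpineGeometry:
        if self._geometry is None:
            self._geometry = geometry_from_mask(
                self.volume, self.mask, self.config.anthropometry
            )
        return self._geometry

    @classmethod
    def from_synthetic(
        cls,
        target_bmd: float,
        seed: int = 0,
        config: RunConfig | None = None,
        noise_seed: int | None = None,
        subject_id: str | None = None,
    ) -> "SpineFEModel":
        """Generate a synthetic subject at a BMD_QCT-L1-3 target (mg/mL)."""
        config = config or RunConfig()
        geom, vol, mask = synthesize_subject(
            target_bmd, geometry_seed=seed, noise_seed=noise_seed, config=config
        )
        return cls(
            vol, mask, config=config, geometry=geom,
            subject_id=subject_id or f"synthetic_bmd{target_bmd:g}_seed{seed}",
        )

    @classmethod
    def from_files(cls, volume_path, mask_path,
                   config: RunConfig | None = None, **kwargs) -> "SpineFEModel":
        return cls(sio.load_ct(volume_path), sio.load_mask(mask_path),
                   config=config, **kwargs)

    def fit(self, compression: bool = True, motions=None) -> "SpineFEResults":
        """Run the pipeline and return the fitted results."""
        cfg = self.config
        if motions is not None:
            cfg = dataclasses.replace(cfg, motions=tuple(motions))
        record = run_subject(
            self.volume, self.mask, cfg, subject_id=self.subject_id,
            geometry=self._geometry, compression=compression,
        )
        return SpineFEResults(model=self, record=record)


@dataclass
class SpineFEResults:
    """Fitted per-subject outcomes (BMD, failure load, ROM) + diagnostics."""

    model: SpineFEModel
    record: SubjectRecord = field(repr=False)

    # -- convenience accessors ----------------------------------------------
    @property
    def bmd_qct_l1_3(self) -> float:
        return self.record.bmd_qct_l1_3

    @property
    def cohort(self) -> str:
        return self.record.cohort

    @property
    def failure_load(self) -> float:
        return self.record.fl

    @property
    def rom(self) -> dict[str, float]:
        return {
            "flexion": self.record.theta_f,
            "extension": self.record.theta_e,
            "lateral_bending": self.record.theta_l,
            "twisting": self.record.theta_t,
        }

    @property
    def load_displacement(self):
        return self.record.compression

    @property
    def moment_angle(self) -> dict:
        return self.record.rom_curves

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.record.to_dict()]).drop(columns=["provenance"])

    def summary(self) -> str:
        r = self.record
        bmd = r.bmd
        lines = [
            "Whole-lumbar-spine FE results",
            "=" * 46,
            f"subject            : {r.subject_id}",
            f"cohort             : {r.cohort}",
            f"BMD_QCT-L1-3       : {r.bmd_qct_l1_3:8.2f} mg/mL",
        ]
        if bmd is not None:
            for lv, q in bmd.bmd_qct.items():
                lines.append(f"  BMD_QCT {lv}       : {q:8.2f} mg/mL")
        if np.isfinite(r.fl):
            lines += [
                f"failure load (FL)  : {r.fl:8.1f} N",
                f"failure displ.     : {r.failure_displacement:8.3f} mm",
            ]
        for name, val in self.rom.items():
            if np.isfinite(val):
                lines.append(f"ROM {name:<15}: {val:8.2f} deg @ "
                             f"{self.model.config.peak_moment:.1f} N*m")
        prov = r.provenance
        lines += [
            "-" * 46,
            f"mesh: {prov.get('n_nodes', '?')} nodes, "
            f"{prov.get('n_elements', '?')} elements "
            f"(edges {self.model.config.edge_vert}/{self.model.config.edge_ivd} mm)",
            f"config digest: {prov.get('config_digest', '?')}",
        ]
        return "\n".join(lines)

    def plot_curves(self, path=None):
        """Load-displacement and moment-angle plots (matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 3.6))
        if self.record.compression is not None:
            c = self.record.compression
            axes[0].plot(c.displacement, c.force, "o-")
            axes[0].set_xlabel("axial displacement (mm)")
            axes[0].set_ylabel("reaction force (N)")
            axes[0].set_title(f"FL = {c.fl:.0f} N")
        for name, mc in self.record.rom_curves.items():
            axes[1].plot(mc.moment, mc.angle, label=name)
        axes[1].set_xlabel("moment (N*m)")
        axes[1].set_ylabel("rotation (deg)")
        axes[1].legend(fontsize=7)
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


class CohortComparison:
    """Cohort-level model: descriptives, correlations and group tests."""

    def __init__(self, records):
        if isinstance(records, pd.DataFrame):
            self.frame = records.copy()
        else:
            self.frame = sio.records_to_frame(list(records))
        if "cohort" not in self.frame:
            raise SpineFEError("cohort records need a 'cohort' column")

    def fit(self, alpha: float = sstats.SIGNIFICANCE_LEVEL) -> "CohortResults":
        table = sstats.build_table3(self.frame, alpha=alpha)
        corr = sstats.correlation_table(self.frame)
        return CohortResults(frame=self.frame, table3=table, correlations=corr,
                             alpha=alpha)


@dataclass
class CohortResults:
    frame: pd.DataFrame = field(repr=False)
    table3: pd.DataFrame
    correlations: pd.DataFrame
    alpha: float

    def summary(self) -> str:
        lines = [
            "Cohort comparison (healthy vs osteoporotic)",
            "=" * 64,
            f"n healthy = {(self.frame['cohort'] == 'healthy').sum()}, "
            f"n osteoporotic = {(self.frame['cohort'] == 'osteoporotic').sum()}",
            "",
        ]
        t = self.table3
        lines.append(f"{'parameter':<24}{'HC mean+-SD':>18}{'OP mean+-SD':>18}"
                     f"{'p':>9}")
        for _, row in t.iterrows():
            star = " *" if row["significant"] else ""
            lines.append(
                f"{row['parameter']:<24}"
                f"{row['healthy_mean']:>10.2f} +- {row['healthy_sd']:<5.2f}"
                f"{row['op_mean']:>10.2f} +- {row['op_sd']:<5.2f}"
                f"{row['p_value']:>8.3g}{star}"
            )
        lines.append("")
        lines.append("correlation with BMD_QCT-L1-3 (Spearman):")
        for _, row in self.correlations.iterrows():
            extra = ""
            if "pearson_r" in row and pd.notna(row.get("pearson_r", np.nan)):
                extra = (f"   [Pearson r = {row['pearson_r']:.2f}, "
                         f"R^2 = {row['r_squared']:.2f}]")
            lines.append(
                f"  {row['parameter']:<22} rho = {row['spearman_rho']:+.2f}, "
                f"p = {row['spearman_p']:.3g}{extra}"
            )
        lines.append(f"\nsignificance marker: p < {self.alpha}")
        return "\n".join(lines)

    def save(self, table_path, correlations_path=None) -> None:
        self.table3.to_csv(table_path, index=False)
        if correlations_path:
            self.correlations.to_csv(correlations_path, index=False)
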