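"""Tissue cell-wall amounts from 2-D section areas.

The internode is treated as a cylinder, so relative tissue volumes equal
relative section areas; no axial integration is performed.  Rind and
bundle areas are taken as 100% cell wall (thick walls, little visible
lumen).  Parenchyma wall amounts come from a spherical-cell model: with
cells of radius R and wall thickness t, the wall volume fraction is
3 t / R.
"""

from __future__ import annotations

from dataclasses import dataclass

DEFAULT_WALL_THICKNESS_UM = 0.5


class StereologyError(ValueError):
    pass


@dataclass(frozen=True)
class StereologyResult:
    """Cell-wall proportions for one section (percentages)."""

    Cw_thickness_um: float
    Pm_CD: float          # middle parenchyma wall density, % volume
    Pr_CD: float          # near-rind parenchyma wall density, % volume
    CW_T: float           # total cell wall, % of stem area
    Pm_Cw: float          # middle parenchyma, % of total cell wall
    Pr_Cw: float          # near-rind parenchyma, % of total cell wall
    Ri_Cw: float          # rind, % of total cell wall
    Vb_Cw: float          # bundles, % of total cell wall

    def __post_init__(self) -> None:
        total = self.Pm_Cw + self.Pr_Cw + self.Ri_Cw + self.Vb_Cw
        if abs(total - 100.0) > 1e-6:
            raise StereologyError(f"wall proportions sum to {total}, not 100")


def cell_wall_density(mean_size_um: float,
                      wall_thickness_um: float = DEFAULT_WALL_THICKNESS_UM) -> float:
    """Spherical-cell wall density (% volume): 3 t / R with R = size / 2."""
    if mean_size_um <= 0:
        raise StereologyError("mean cell size must be positive")
    if wall_thickness_um < 0:
        raise StereologyError("wall thickness must be non-negative")
    if wall_thickness_um > 0 and mean_size_um <= 2 * wall_thickness_um:
        raise StereologyError("cell size must exceed twice the wall thickness")
    radius = mean_size_um / 2.0
    return 3.0 * wall_thickness_um / radius * 100.0


def parenchyma_wall_amounts(Pa_A_cm2: float, middle_area_cm2: float,
                            Pm_CD_pct: float, Pr_CD_pct: float) -> tuple[float, float]:
    """Wall areas (cm^2) of the two parenchyma zones.

    The near-rind zone is the total parenchyma minus the middle zone, so
    it also absorbs the 500-1000 um transition band.
    """
    if middle_area_cm2 > Pa_A_cm2:
        raise StereologyError("middle parenchyma area exceeds total parenchyma area")
    Pm_wall = Pm_CD_pct / 100.0 * middle_area_cm2
    Pr_wall = Pr_CD_pct / 100.0 * (Pa_A_cm2 - middle_area_cm2)
    return Pm_wall, Pr_wall


def tissue_wall_proportions(Ri_A_est_cm2: float, Vb_A_cm2: float,
                            Pm_wall_cm2: float, Pr_wall_cm2: float,
                            St_A_cm2: float,
                            Pm_CD_pct: float = float("nan"),
                            Pr_CD_pct: float = float("nan"),
                            wall_thickness_um: float = DEFAULT_WALL_THICKNESS_UM,
                            ) -> StereologyResult:
    """Total cell wall and its split over the four tissues.

    total = rind + bundles + parenchyma wall amounts; each tissue is
    reported as a percentage of that total, and ``CW_T`` as the total
    relative to the stem area.
    """
    for name, v in (("rind", Ri_A_est_cm2), ("bundles", Vb_A_cm2),
                    ("Pm wall", Pm_wall_cm2), ("Pr wall", Pr_wall_cm2)):
        if v < 0:
            raise StereologyError(f"negative {name} area")
    total = Ri_A_est_cm2 + Vb_A_cm2 + Pm_wall_cm2 + Pr_wall_cm2
    if total <= 0:
        raise StereologyError("total cell wall amount is zero")
    if St_A_cm2 <= 0:
        raise StereologyError("stem area must be positive")
    return StereologyResult(
        Cw_thickness_um=wall_thickness_um,
        Pm_CD=Pm_CD_pct, Pr_CD=Pr_CD_pct,
        CW_T=total / St_A_cm2 * 100.0,
        Pm_Cw=Pm_wall_cm2 / total * 100.0,
        Pr_Cw=Pr_wall_cm2 / total * 100.0,
        Ri_Cw=Ri_A_est_cm2 / total * 100.0,
        Vb_Cw=Vb_A_cm2 / total * 100.0,
    )


def section_stereology(Pa_A_cm2: float, middle_area_cm2: float,
                       Ri_A_est_cm2: float, Vb_A_cm2: float, St_A_cm2: float,
                       Pm_mean_size_um: float, Pr_mean_size_um: float,
                       wall_thickness_um: float = DEFAULT_WALL_THICKNESS_UM,
                       ) -> StereologyResult:
    """End-to-end stereology for one section from descriptor inputs."""
    Pm_CD = cell_wall_density(Pm_mean_size_um, wall_thickness_um)
    Pr_CD = cell_wall_density(Pr_mean_size_um, wall_thickness_um)
    Pm_wall, Pr_wall = parenchyma_wall_amounts(Pa_A_cm2, middle_area_cm2, Pm_CD, Pr_CD)
    return tissue_wall_proportions(Ri_A_est_cm2, Vb_A_cm2, Pm_wall, Pr_wall,
                                   St_A_cm2, Pm_CD, Pr_CD, wall_thickness_um)
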