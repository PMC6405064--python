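"""Package-wide physical constants and configurable defaults.

Values here are the single source of truth for the simulator and the
densitometry defaults; the CLI can override the ``DEFAULTS`` entries via a
flat key=value config file (see :func:`load_config`).
"""

from __future__ import annotations

from pathlib import Path

#: Density of pure calcite crystal (g/cm^3); maps to CCN = 1000.
CALCITE_DENSITY = 2.71

#: X-ray tube voltage ceiling for simulated spectra (keV).
MAX_TUBE_KEV = 80.0

#: Lower bound of the validity range of the attenuation model (keV).
MIN_KEV = 5.0

# Two-term attenuation model mu = density * (ATTEN_A * E^-3 + ATTEN_B),
# mu in 1/um, density in g/cm^3, E in keV.  The absolute scale is
# arbitrary (CCN is scale-free); ATTEN_A/ATTEN_B are fixed so that pure
# calcite at 40 keV has mu ~ 0.1 /um and the photoelectric term dominates
# below ~30 keV, which is what produces beam hardening.
ATTEN_A = 2000.0
ATTEN_B = 0.005

#: Mass attenuation of aluminium for the optional 0.2 mm pre-filter,
#: same two-term model shape evaluated at aluminium density 2.70 g/cm^3.
AL_FILTER_DENSITY = 2.70
AL_FILTER_THICKNESS_UM = 200.0

DEFAULTS: dict[str, float | int | str] = {
    # densitometry
    "ccn_k": 1000,
    "segmentation_min_component": 1000,
    "histogram_bins": 50,
    "histogram_lo": 0.0,
    "histogram_hi": 1200.0,
    "calibration_min_voxels": 100,
    "summary_statistic": "mean",
    # phantom / scan
    "voxel_size_um": 0.8,
    "phantom_grid": 128,
    "wall_thickness_um": 4.0,
    "n_angles": 360,
    "spectrum_bins": 12,
    # pipeline
    "alpha": 0.05,
    "weight_range_min_ug": 3.0,
}


def load_config(path: str | Path | None) -> dict:
    """Read a flat ``key = value`` config file and merge over DEFAULTS.

    Lines starting with ``#`` and blank lines are ignored.  Values are
    parsed as int, then float, then kept as strings.
    """
    cfg = dict(DEFAULTS)
    if path is None:
        return cfg
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        for cast in (int, float):
            try:
                cfg[key] = cast(val)
                break
            except ValueError:
                continue
        else:
            cfg[key] = val
    return cfg
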