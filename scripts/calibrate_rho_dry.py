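#!/usr/bin/env python
"""One-off calibration of the dry-solids density default.

The burial chain needs a dry-solids density rho_dry that no measurement
fixes directly.  This script solves for the density at which the anchored
solids flux (1 - phi) * omega = 0.1812 * 1.2 mm yr-1, carrying the
midpoint organic-carbon fraction (TOC = 0.15), buries exactly
5.5 mmolC m-2 d-1 of organic carbon — the reported average flux.  The
result is frozen as ``lakecarbon.sediment.RHO_DRY_DEFAULT``.
"""

from lakecarbon.sediment import (
    RHO_DRY_DEFAULT,
    BurialInputs,
    calibrate_rho_dry,
    organic_burial_flux,
)

rho = calibrate_rho_dry(target_flux=5.5, toc_frac=0.15)
print(f"calibrated rho_dry = {rho!r} kg m-3")
print(f"packaged default   = {RHO_DRY_DEFAULT!r} kg m-3")
check = organic_burial_flux(BurialInputs(toc_frac=0.15, rho_dry=rho), phi=0.94)
print(f"check: burial flux at TOC 0.15 -> {check:.6f} mmolC m-2 d-1 (target 5.5)")
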