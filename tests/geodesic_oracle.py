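"""Independent geodesic distance oracle: Vincenty's inverse formula on the
WGS84 ellipsoid. Used only to bound the error of the package's spherical
haversine distances; kept deliberately separate from the implementation."""

import math

WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
WGS84_B = WGS84_A * (1.0 - WGS84_F)


def vincenty_km(lat1, lon1, lat2, lon2, tol=1e-12, max_iter=200):
    if (lat1, lon1) == (lat2, lon2):
        return 0.0
    u1 = math.atan((1 - WGS84_F) * math.tan(math.radians(lat1)))
    u2 = math.atan((1 - WGS84_F) * math.tan(math.radians(lat2)))
    ll = math.radians(lon2 - lon1)
    lam = ll
    su1, cu1 = math.sin(u1), math.cos(u1)
    su2, cu2 = math.sin(u2), math.cos(u2)
    for _ in range(max_iter):
        sl, cl = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(cu2 * sl, cu1 * su2 - su1 * cu2 * cl)
        if sin_sigma == 0:
            return 0.0
        cos_sigma = su1 * su2 + cu1 * cu2 * cl
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cu1 * cu2 * sl / sin_sigma
        cos2_alpha = 1.0 - sin_alpha**2
        cos2_sigma_m = 0.0 if cos2_alpha == 0 else cos_sigma - 2 * su1 * su2 / cos2_alpha
        c = WGS84_F / 16 * cos2_alpha * (4 + WGS84_F * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = ll + (1 - c) * WGS84_F * sin_alpha * (
            sigma + c * sin_sigma * (cos2_sigma_m + c * cos_sigma * (-1 + 2 * cos2_sigma_m**2))
        )
        if abs(lam - lam_prev) < tol:
            break
    u2_ = cos2_alpha * (WGS84_A**2 - WGS84_B**2) / WGS84_B**2
    a = 1 + u2_ / 16384 * (4096 + u2_ * (-768 + u2_ * (320 - 175 * u2_)))
    b = u2_ / 1024 * (256 + u2_ * (-128 + u2_ * (74 - 47 * u2_)))
    d_sigma = b * sin_sigma * (
        cos2_sigma_m
        + b / 4 * (
            cos_sigma * (-1 + 2 * cos2_sigma_m**2)
            - b / 6 * cos2_sigma_m * (-3 + 4 * sin_sigma**2) * (-3 + 4 * cos2_sigma_m**2)
        )
    )
    return WGS84_B * a * (sigma - d_sigma) / 1000.0
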