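import logging

import numpy as np
import pytest

from corofuse.geometry import Contour2D

logging.getLogger("corofuse").setLevel(logging.ERROR)


def circle_contour(r=1.0, n=360, center=(0.0, 0.0)):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Contour2D(np.column_stack([center[0] + r * np.cos(th),
                                      center[1] + r * np.sin(th)]))


def ellipse_contour(a=2.0, b=1.0, n=256, angle_deg=0.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([a * np.cos(th), b * np.sin(th)])
    ang = np.radians(angle_deg)
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    return Contour2D(pts @ R.T)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def pipeline_results():
    """Run the full synthetic loop once per preset and share the results.

    Used by the end-to-end tests; session scope keeps the suite within a
    small multiple of one pipeline run.
    """
    from corofuse.fusion import (LabeledPointCloud, fuse,
                                 remove_overlapping_points,
                                 reconstruct_surface)
    from corofuse.oct_processing import Calibration, process_pullback
    from corofuse.phantom import (build_phantom, iter_rendered_frames,
                                  make_ccta_like_cloud, n_pullback_frames,
                                  phantom_landmarks, preset_spec,
                                  smooth_twist_profile)
    from corofuse.registration import correct_twist, register_pullback
    from corofuse.validation import lumen_area_profile, stenosis_from_profile

    results = {}
    for preset, seed in (("patient12-like", 3), ("patient7-like", 11)):
        spec = preset_spec(preset, seed=seed)
        mesh, truth = build_phantom(spec)
        cal = Calibration(frame_spacing_mm=0.4)
        truth.twist_profile = smooth_twist_profile(
            n_pullback_frames(truth, cal), max_rate_deg=1.0, seed=seed + 1)
        series = process_pullback(iter_rendered_frames(truth, cal), cal)
        corrected = correct_twist(series)
        stack = register_pullback(corrected, truth.centerline,
                                  phantom_landmarks(truth, cal))
        ccta = make_ccta_like_cloud(mesh, truth)
        oct_pts = stack.all_points()
        filtered = remove_overlapping_points(
            ccta, LabeledPointCloud(oct_pts,
                                    np.full(len(oct_pts), "OCT", object)))
        fused = fuse(filtered, stack)
        lumen = reconstruct_surface(fused, stack.centerline)
        profile = lumen_area_profile(lumen, stack.centerline)
        stenosis = stenosis_from_profile(profile)
        results[preset] = {
            "spec": spec, "mesh": mesh, "truth": truth, "cal": cal,
            "series": corrected, "stack": stack, "fused": fused,
            "lumen": lumen, "profile": profile, "stenosis": stenosis,
        }
    return results
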