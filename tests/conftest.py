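import numpy as np
import pytest

import regenquant as rq


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Small noiseless section with moderate marker fractions."""
    params = rq.PhantomParams(
        n_fibers=80, pixel_size=1.0, noise_sd=0.0,
        frac_emhc=0.2, frac_igg=0.1, seed=11,
    )
    return rq.generate_phantom(params)


@pytest.fixture(scope="session")
def segmented(noiseless_phantom):
    lm = rq.segment_fibers(
        noiseless_phantom.channel("laminin"),
        pixel_size=noiseless_phantom.params.pixel_size,
    )
    return noiseless_phantom, lm


@pytest.fixture(scope="session")
def reference_cohort():
    return rq.load_reference_cohort()


@pytest.fixture(scope="session")
def reference_summaries(reference_cohort):
    return rq.summaries_from_cohort_table(reference_cohort)


def rasterize_convex(points, shape=(100, 100)):
    """Filled convex hull of a 2-D point cloud as a boolean mask."""
    from scipy.spatial import ConvexHull
    from skimage.draw import polygon

    hull = ConvexHull(points)
    rr, cc = polygon(points[hull.vertices, 0], points[hull.vertices, 1], shape)
    mask = np.zeros(shape, bool)
    mask[rr, cc] = True
    return mask


def brute_force_min_feret(mask, step_deg=0.05):
    """Independent minimal-width oracle: dense sweep of caliper directions."""
    from regenquant.morphometry import mask_hull_points

    pts = mask_hull_points(mask)
    thetas = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    dirs = np.stack([np.sin(thetas), np.cos(thetas)], axis=1)
    proj = pts @ dirs.T  # (n_points, n_angles)
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min())
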