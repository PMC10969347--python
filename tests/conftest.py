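import numpy as np
import pytest
from hypothesis import settings

import nasalrecon as nr

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def template():
    return nr.make_template(33)


@pytest.fixture(scope="session")
def template_small():
    return nr.make_template(17)


@pytest.fixture(scope="session")
def graph(template):
    return nr.build_face_graph(template.mesh, n_levels=4)


@pytest.fixture(scope="session")
def population_model(template):
    return nr.PopulationModel.build(template, seed=5)


@pytest.fixture(scope="session")
def population(template, population_model):
    """The 60-face training cohort of the scaled benchmark conditions."""
    return nr.sample_population(template, population_model, 60, seed=9)


@pytest.fixture(scope="session")
def init_params(template, graph):
    """Untrained (initialized) model on the session template."""
    from nasalrecon import autoencoder, nn

    return autoencoder.init_model(
        template.mesh, graph, nn.ModelConfig(latent_dim=32, seed=7)
    )


@pytest.fixture(scope="session")
def trained(template, graph, population, population_model):
    """One trained model shared by every test that needs convergence.

    Study conditions: 60 faces split 17:2:1, rank-8 population, D=32.
    """
    from nasalrecon import autoencoder, nn

    cfg = autoencoder.TrainConfig(
        epochs=400,
        patience=60,
        lr_patience=25,
        seed=2,
        model_config=nn.ModelConfig(latent_dim=32),
    )
    params, history = autoencoder.train(population, graph, cfg)
    return params, history


def disk_mesh(n_rim: int = 12, radius: float = 10.0) -> nr.StructuredMesh:
    """Flat fan disk: centre vertex + n_rim rim vertices, CCW from +z."""
    ang = np.linspace(0, 2 * np.pi, n_rim, endpoint=False)
    verts = np.vstack(
        [[0.0, 0.0, 0.0], np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(n_rim)])]
    )
    faces = np.array([[0, 1 + i, 1 + (i + 1) % n_rim] for i in range(n_rim)])
    return nr.StructuredMesh(verts, faces)


def tetrahedron() -> nr.StructuredMesh:
    verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return nr.StructuredMesh(verts, faces)


def grid_mesh(nx: int = 6, ny: int = 6, spacing: float = 1.0) -> nr.StructuredMesh:
    """Open flat grid sheet in the z=0 plane."""
    xs, ys = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing, indexing="xy")
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(nx * ny)])
    faces = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a = j * nx + i
            faces.append((a, a + 1, a + nx + 1))
            faces.append((a, a + nx + 1, a + nx))
    return nr.StructuredMesh(verts, np.array(faces))


def point_triangle_distance(p, a, b, c):
    """Scalar closest-distance oracle (region-by-region projection),
    independent of the library's vectorized implementation."""
    p, a, b, c = (np.asarray(x, dtype=float) for x in (p, a, b, c))
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return np.linalg.norm(p - a)
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return np.linalg.norm(p - b)
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        t = d1 / (d1 - d3)
        return np.linalg.norm(p - (a + t * ab))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return np.linalg.norm(p - c)
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        t = d2 / (d2 - d6)
        return np.linalg.norm(p - (a + t * ac))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return np.linalg.norm(p - (b + t * (c - b)))
    denom = va + vb + vc
    v, w = vb / denom, vc / denom
    return np.linalg.norm(p - (a + v * ab + w * ac))


def random_mesh(rng, n_tris=40, scale=10.0):
    """Triangle soup with shared random vertices (possibly disconnected)."""
    nv = max(6, n_tris // 2)
    verts = rng.uniform(-scale, scale, size=(nv, 3))
    faces = []
    while len(faces) < n_tris:
        tri = rng.choice(nv, size=3, replace=False)
        faces.append(tri)
    return nr.StructuredMesh(verts, np.array(faces))
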