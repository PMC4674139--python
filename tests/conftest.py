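"""Shared fixtures: toy complexes and synthetic corpora with ground truth."""

import numpy as np
import pytest

from dockmine.synth import ComplexSpec, CorpusSpec, generate_complex, generate_corpus


@pytest.fixture(scope="session")
def toy():
    """A deterministic two-chain toy complex with recorded ground truth."""
    return generate_complex(ComplexSpec(seed=42))


@pytest.fixture(scope="session")
def corpus_with_truth():
    """A synthetic corpus (separated classes, planted mentions) + truth table."""
    return generate_corpus(CorpusSpec(seed=42, n_pos=60, n_neg=60))


def brute_force_interface(res1, res2, cutoff=6.0):
    """O(n^2) all-pairs heavy-atom distance scan (test oracle)."""
    iface1, iface2 = set(), set()
    for r1 in res1:
        for r2 in res2:
            d = np.linalg.norm(r1.coords[:, None, :] - r2.coords[None, :, :], axis=2)
            if (d <= cutoff).any():
                iface1.add(r1.id)
                iface2.add(r2.id)
    return iface1, iface2


def grid_sasa(structure, chains=None, probe=1.4, n_theta=25, n_phi=40):
    """Independent SASA oracle: equal-area latitude/longitude point grid and
    a brute-force occlusion loop (no spatial index, different point set from
    the implementation's golden-spiral lattice)."""
    from dockmine.surface import DEFAULT_VDW, VDW_RADII

    residues = structure.residues(chains)
    coords = np.vstack([r.coords for r in residues])
    radii = np.array(
        [VDW_RADII.get(el, DEFAULT_VDW) + probe for r in residues for el in r.elements]
    )
    res_index = np.repeat(np.arange(len(residues)), [len(r.coords) for r in residues])

    z = (np.arange(n_theta) + 0.5) / n_theta * 2.0 - 1.0
    phi = 2.0 * np.pi * (np.arange(n_phi) + 0.5) / n_phi
    zz, pp = np.meshgrid(z, phi, indexing="ij")
    s = np.sqrt(1.0 - zz**2)
    sphere = np.column_stack([(s * np.cos(pp)).ravel(), (s * np.sin(pp)).ravel(), zz.ravel()])

    areas = np.zeros(len(residues))
    for i in range(len(coords)):
        pts = coords[i] + radii[i] * sphere
        exposed = np.ones(len(pts), dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 >= radii[j] ** 2
        areas[res_index[i]] += exposed.mean() * 4.0 * np.pi * radii[i] ** 2
    return {res.id: areas[k] for k, res in enumerate(residues)}
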