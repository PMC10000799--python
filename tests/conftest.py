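import numpy as np
import pytest

from sxfh import constants
from sxfh import structure_io as sio
from sxfh.hologram_model import GridSpec, cluster_hologram, superpose_holograms


def rot_x(deg):
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])


def rot_z(deg):
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


def rotate_cluster(cluster, R):
    """Rigidly rotate a cluster's atoms (crystal -> lab frame)."""
    em = sio.AtomSite(cluster.emitter.element, cluster.emitter.label,
                      R @ cluster.emitter.position,
                      cluster.emitter.occupancy)
    sc = [sio.AtomSite(s.element, s.label, R @ s.position, s.occupancy)
          for s in cluster.scatterers]
    return sio.EmitterCluster(em, sc, u2rel=cluster.u2rel)


@pytest.fixture(scope="session")
def k_mn():
    return constants.K_MN_KALPHA


@pytest.fixture(scope="session")
def oec_structure():
    atoms, cell = sio.read_structure(sio.bundled_structure_path())
    return atoms, cell


@pytest.fixture(scope="session")
def oec_expanded(oec_structure):
    atoms, cell = oec_structure
    expanded = sio.expand_unit_cell(atoms, cell)
    sio.assign_oec_valence(expanded)
    return expanded


@pytest.fixture(scope="session")
def oec_clusters(oec_expanded):
    return sio.extract_clusters(oec_expanded, u2rel=0.35)


@pytest.fixture(scope="session")
def coarse_spec():
    """3-degree grid: enough resolution for statistics, 9x fewer nodes."""
    return GridSpec(theta_max=90.0, theta_step=3.0, phi_step=3.0)


@pytest.fixture(scope="session")
def mn_dimer():
    em = sio.AtomSite("Mn", "MN_E", [0.0, 0.0, 0.0])
    sc = sio.AtomSite("Mn", "MN_S", [0.0, 0.0, 2.89])
    return em, sc


def superposed_hologram(clusters, k, spec):
    return superpose_holograms([cluster_hologram(c, k, spec)
                                for c in clusters])
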