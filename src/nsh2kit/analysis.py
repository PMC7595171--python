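"""Conformational-state analysis: superposition, core-fit PCA, subvector
coupling, order parameters, correlations, and alpha/beta classification.

The workflow mirrors the essential-dynamics treatment of a two-state SH2
domain: frames are least-squares fitted on the rigid core of the domain,
PCA is run over the backbone analysis set, the dominant collective vector is
split into subvectors describing the pY loop and the +5 site, and frames are
classified as alpha (pY loop closed, +5 site closed), beta (both open) or
mixed from three inter-atom order parameters:

* pY-loop opening   = |Lys35 CA - Thr42 CA|   (~9 A alpha, ~11 A beta)
* sheet spread      = |Gly39 C  - Asn58 N |   (~12 A alpha, ~4 A beta)
* +5-site opening   = |Tyr66 CA - Leu88 CA|   (~7 A alpha, ~12 A beta)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import A_PER_NM, nm_to_angstrom
from .ensembles import SelectionSpec, StructureEnsemble
from .model_systems import ANCHORS

__all__ = [
    "CollectiveVector",
    "OrderParameterSeries",
    "StateClassification",
    "DEFAULT_THRESHOLDS",
    "superpose",
    "pca",
    "project",
    "subvector",
    "order_parameters",
    "pearson",
    "classify_states",
    "classify_by_projection",
    "write_collective_vector",
    "read_collective_vector",
]

#: Default classification thresholds (Angstrom): midpoints of the alpha/beta
#: reference values for each order parameter.
DEFAULT_THRESHOLDS = {"pY": 10.0, "sheet": 8.0, "plus5": 9.5}


# ---------------------------------------------------------------------------
# Superposition (Kabsch)
# ---------------------------------------------------------------------------

def _kabsch(moving: np.ndarray, target: np.ndarray):
    """Optimal rotation R (proper) such that moving @ R.T ~ target.

    Both inputs must already be centered.
    """
    h = moving.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def _check_fit_selection(coords: np.ndarray, what: str):
    if coords.shape[0] < 3:
        raise ValueError(f"{what}: fit selection has fewer than 3 atoms")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise ValueError(f"{what}: fit selection atoms are collinear")


def superpose(ensemble: StructureEnsemble, reference: StructureEnsemble,
              fit_selection: SelectionSpec):
    """Least-squares fit every frame onto the reference.

    The optimal rigid-body (Kabsch) transform is computed on the fit
    selection and applied to all atoms.  Returns the superposed ensemble and
    the per-frame RMSD (Angstrom) over the fit selection.
    """
    idx = fit_selection.resolve(ensemble)
    ref_idx = fit_selection.resolve(reference)
    if len(idx) != len(ref_idx):
        raise ValueError("fit selection resolves differently on ensemble and reference")
    ref = reference.coordinates[0, ref_idx]
    _check_fit_selection(ref, "superpose")
    ref_centroid = ref.mean(axis=0)
    ref_centered = ref - ref_centroid

    out = np.empty_like(ensemble.coordinates)
    rmsd = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        sel = ensemble.coordinates[f, idx]
        centroid = sel.mean(axis=0)
        rot = _kabsch(sel - centroid, ref_centered)
        out[f] = (ensemble.coordinates[f] - centroid) @ rot.T + ref_centroid
        diff = out[f, idx] - ref
        rmsd[f] = nm_to_angstrom(np.sqrt((diff**2).sum(axis=1).mean()))
    return ensemble.with_coordinates(out), rmsd


# ---------------------------------------------------------------------------
# PCA and collective vectors
# ---------------------------------------------------------------------------

@dataclass
class CollectiveVector:
    """Mean structure plus a unit displacement mode over a selection.

    The projection of a frame is eta = dot(frame - mean, vector), in nm;
    eta over the generating ensemble has variance equal to ``eigenvalue``.
    """

    mean_structure: np.ndarray  # (n_sel, 3), nm
    vector: np.ndarray  # (n_sel, 3), unit Frobenius norm
    eigenvalue: float  # nm^2
    variance_fraction: float
    residue_numbers: np.ndarray  # labels of the selected atoms, in order
    atom_names: np.ndarray

    def __post_init__(self):
        nrm = np.linalg.norm(self.vector)
        if abs(nrm - 1.0) > 1e-8:
            raise ValueError(f"vector norm {nrm} is not 1")
        if self.eigenvalue < -1e-12:
            raise ValueError("negative eigenvalue")

    def resolve_indices(self, ensemble: StructureEnsemble) -> np.ndarray:
        """Atom indices of this vector's selection on another ensemble."""
        return np.array(
            [ensemble.atom_index(int(r), str(a))
             for r, a in zip(self.residue_numbers, self.atom_names)]
        )


def _orient(vec: np.ndarray, mean: np.ndarray, resnum, atom_names) -> np.ndarray:
    """Fix the arbitrary eigenvector sign: increasing eta must increase the
    sheet-spread distance (toward the alpha state).  Falls back to making the
    largest-magnitude component positive when the sheet anchors are not part
    of the selection."""
    (r1, n1), (r2, n2) = ANCHORS["sheet"]
    sel = {(int(r), str(a)): i for i, (r, a) in enumerate(zip(resnum, atom_names))}
    if (r1, n1) in sel and (r2, n2) in sel:
        i, j = sel[(r1, n1)], sel[(r2, n2)]
        eps = 0.1
        d_plus = np.linalg.norm((mean + eps * vec)[j] - (mean + eps * vec)[i])
        d_minus = np.linalg.norm((mean - eps * vec)[j] - (mean - eps * vec)[i])
        if d_plus < d_minus:
            return -vec
        return vec
    k = np.argmax(np.abs(vec))
    return vec if vec.flat[k] >= 0 else -vec


def pca(ensemble: StructureEnsemble, analysis_selection: SelectionSpec,
        fit_selection: SelectionSpec | None = None, n_vectors: int = 1,
        reference: StructureEnsemble | None = None):
    """Essential-dynamics PCA of the atom-coordinate covariance matrix.

    When ``fit_selection`` is given the ensemble is superposed internally
    onto ``reference`` (default: its own first frame) before the covariance
    is accumulated; otherwise the ensemble is assumed already superposed.
    Vectors are sorted by descending eigenvalue; ``variance_fraction`` is
    eigenvalue / trace of the covariance matrix.
    """
    if ensemble.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    if fit_selection is not None:
        ref = reference if reference is not None else ensemble.frame(0)
        ensemble, _ = superpose(ensemble, ref, fit_selection)
    idx = analysis_selection.resolve(ensemble)
    data = ensemble.coordinates[:, idx, :].reshape(ensemble.n_frames, -1)
    mean = data.mean(axis=0)
    centered = data - mean
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    eigvals = svals**2 / (ensemble.n_frames - 1)
    total = eigvals.sum()
    n_vectors = min(n_vectors, len(eigvals))
    mean_structure = mean.reshape(-1, 3)
    resnum = ensemble.residue_numbers[idx]
    atom_names = ensemble.atom_names[idx]
    out = []
    for k in range(n_vectors):
        vec = _orient(vt[k].reshape(-1, 3), mean_structure, resnum, atom_names)
        out.append(
            CollectiveVector(
                mean_structure=mean_structure.copy(),
                vector=vec,
                eigenvalue=float(eigvals[k]),
                variance_fraction=float(eigvals[k] / total) if total > 0 else 0.0,
                residue_numbers=resnum.copy(),
                atom_names=atom_names.copy(),
            )
        )
    return out


def project(ensemble: StructureEnsemble, cv: CollectiveVector) -> np.ndarray:
    """Per-frame projection eta_t = dot(frame_t - mean, vector), in nm."""
    idx = cv.resolve_indices(ensemble)
    data = ensemble.coordinates[:, idx, :]
    return np.einsum("fij,ij->f", data - cv.mean_structure[None], cv.vector)


def subvector(cv: CollectiveVector, ensemble: StructureEnsemble,
              subset: SelectionSpec) -> CollectiveVector:
    """Subvector of a collective vector over a subset of its atoms.

    Two-step construction: (1) rebuild the rank-1 trajectory
    mean + eta_t * vector from the ensemble's projections, (2) run PCA on
    that reconstruction restricted to the subset atoms; the first vector is
    returned.  In closed form this equals the restriction of ``cv.vector``
    to the subset renormalized to unit length (up to sign); the equivalence
    is asserted internally.
    """
    sub_idx_ens = subset.resolve(ensemble)
    cv_idx_ens = cv.resolve_indices(ensemble)
    pos_in_cv = {int(a): i for i, a in enumerate(cv_idx_ens)}
    try:
        sub_pos = np.array([pos_in_cv[int(a)] for a in sub_idx_ens])
    except KeyError as exc:
        raise ValueError("subset is not contained in the vector's selection") from exc

    restriction = cv.vector[sub_pos]
    rnorm = np.linalg.norm(restriction)
    if rnorm < 1e-8:
        raise ValueError(
            "subset carries no weight in the collective vector (restriction norm "
            f"{rnorm:.2e})"
        )
    eta = project(ensemble, cv)
    if np.ptp(eta) == 0:
        raise ValueError("projections are constant; subvector undefined")
    # rank-1 reconstruction restricted to the subset
    recon = cv.mean_structure[None, sub_pos, :] + eta[:, None, None] * restriction[None]
    flat = recon.reshape(len(eta), -1)
    centered = flat - flat.mean(axis=0)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    vec = vt[0].reshape(-1, 3)
    ref = restriction / rnorm
    agreement = abs(float(np.sum(vec * ref)))
    assert agreement >= 0.999, (
        f"subvector/restriction equivalence violated (|dot| = {agreement:.6f})"
    )
    if float(np.sum(vec * ref)) < 0:
        vec = -vec
    eig = float(svals[0] ** 2 / (len(eta) - 1))
    total = float((svals**2).sum() / (len(eta) - 1))
    return CollectiveVector(
        mean_structure=cv.mean_structure[sub_pos].copy(),
        vector=vec,
        eigenvalue=eig,
        variance_fraction=eig / total if total > 0 else 0.0,
        residue_numbers=cv.residue_numbers[sub_pos].copy(),
        atom_names=cv.atom_names[sub_pos].copy(),
    )


# ---------------------------------------------------------------------------
# Order parameters and classification
# ---------------------------------------------------------------------------

@dataclass
class OrderParameterSeries:
    """Per-frame pY-loop, sheet-spread and +5-site distances in Angstrom."""

    pY: np.ndarray
    sheet: np.ndarray
    plus5: np.ndarray

    def __len__(self):
        return len(self.pY)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name in ("pY", "sheet", "plus5"):
            vals = getattr(self, name)
            rows.append(pd.DataFrame({
                "frame": np.arange(len(vals)), "name": name,
                "value": vals, "unit": "angstrom",
            }))
        return pd.concat(rows, ignore_index=True)


def order_parameters(ensemble: StructureEnsemble) -> OrderParameterSeries:
    """The three state order parameters, in Angstrom, for every frame."""
    series = {}
    for key, ((r1, n1), (r2, n2)) in ANCHORS.items():
        i, j = ensemble.atom_index(r1, n1), ensemble.atom_index(r2, n2)
        d = np.linalg.norm(
            ensemble.coordinates[:, j, :] - ensemble.coordinates[:, i, :], axis=1
        )
        series[key] = nm_to_angstrom(d)
    return OrderParameterSeries(pY=series["pY"], sheet=series["sheet"],
                                plus5=series["plus5"])


def pearson(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance series")
    return float(stats.pearsonr(x, y).statistic)


def _wilson(k: int, n: int):
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(k) / n, float(lo), float(hi)


@dataclass
class StateClassification:
    """Per-frame alpha/beta/mixed labels with provenance.

    ``fractions`` maps each state to (fraction, wilson_low, wilson_high) at
    95% confidence.
    """

    labels: np.ndarray
    thresholds: dict
    fractions: dict
    log: list = field(default_factory=list)

    @property
    def alpha_fraction(self) -> float:
        return self.fractions["alpha"][0]


def classify_states(ops: OrderParameterSeries,
                    thresholds: dict | None = None) -> StateClassification:
    """Quadrant classification from the pY-loop and +5-site order parameters.

    alpha: pY loop closed AND +5 site closed (both below threshold);
    beta: both open; mixed: the two off-diagonal quadrants.  Thresholds
    default to the midpoints of the alpha/beta reference distances and are
    recorded on the result.
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    log = []
    for key in ("pY", "plus5"):
        vals = getattr(ops, key)
        if not (vals.min() <= thr[key] <= vals.max()):
            log.append(
                f"threshold {key}={thr[key]} A outside the data range "
                f"[{vals.min():.2f}, {vals.max():.2f}] A"
            )
    py_closed = ops.pY < thr["pY"]
    p5_closed = ops.plus5 < thr["plus5"]
    labels = np.full(len(ops), "mixed", dtype=object)
    labels[py_closed & p5_closed] = "alpha"
    labels[~py_closed & ~p5_closed] = "beta"
    n = len(labels)
    fractions = {
        state: _wilson(int(np.sum(labels == state)), n)
        for state in ("alpha", "beta", "mixed")
    }
    return StateClassification(labels=labels, thresholds=thr,
                               fractions=fractions, log=log)


def classify_by_projection(ensemble: StructureEnsemble,
                           py_subvector: CollectiveVector,
                           plus5_subvector: CollectiveVector,
                           alpha_reference: StructureEnsemble,
                           beta_reference: StructureEnsemble) -> StateClassification:
    """Alternative classification in the plane of the two subvector
    projections, with thresholds at the midpoint of the projected alpha/beta
    reference geometries."""
    out = {}
    for tag, cv in (("py", py_subvector), ("plus5", plus5_subvector)):
        eta = project(ensemble, cv)
        a = float(project(alpha_reference, cv)[0])
        b = float(project(beta_reference, cv)[0])
        if a == b:
            raise ValueError(f"references project identically on the {tag} subvector")
        out[tag] = (eta, 0.5 * (a + b), a < b)
    (eta_py, thr_py, alpha_low_py) = out["py"]
    (eta_p5, thr_p5, alpha_low_p5) = out["plus5"]
    is_a_py = eta_py < thr_py if alpha_low_py else eta_py > thr_py
    is_a_p5 = eta_p5 < thr_p5 if alpha_low_p5 else eta_p5 > thr_p5
    labels = np.full(len(eta_py), "mixed", dtype=object)
    labels[is_a_py & is_a_p5] = "alpha"
    labels[~is_a_py & ~is_a_p5] = "beta"
    n = len(labels)
    fractions = {
        state: _wilson(int(np.sum(labels == state)), n)
        for state in ("alpha", "beta", "mixed")
    }
    return StateClassification(
        labels=labels,
        thresholds={"eta_py": thr_py, "eta_plus5": thr_p5, "unit": "nm"},
        fractions=fractions,
    )


# ---------------------------------------------------------------------------
# Collective-vector JSON I/O
# ---------------------------------------------------------------------------

def write_collective_vector(cv: CollectiveVector, path) -> None:
    doc = {
        "residue_numbers": [int(r) for r in cv.residue_numbers],
        "atom_names": [str(a) for a in cv.atom_names],
        "mean_structure_nm": cv.mean_structure.tolist(),
        "vector": cv.vector.tolist(),
        "eigenvalue_nm2": cv.eigenvalue,
        "variance_fraction": cv.variance_fraction,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_collective_vector(path) -> CollectiveVector:
    with open(path) as fh:
        doc = json.load(fh)
    return CollectiveVector(
        mean_structure=np.array(doc["mean_structure_nm"]),
        vector=np.array(doc["vector"]),
        eigenvalue=float(doc["eigenvalue_nm2"]),
        variance_fraction=float(doc["variance_fraction"]),
        residue_numbers=np.array(doc["residue_numbers"]),
        atom_names=np.array(doc["atom_names"], dtype=object),
    )
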