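"""Contact detection and kinetics from trajectories.

Residue-residue contacts use a dual-cutoff (hysteresis) scheme: a
contact forms when any two heavy atoms, one from each residue, come
within 0.38 nm, and is only broken once the closest heavy-atom distance
exceeds 0.8 nm; excursions through the intermediate band do not break
the contact, suppressing boundary-recrossing artifacts. Intra-chain
pairs separated by fewer than 4 residues in sequence are excluded.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TrajectoryFrames, atom_masses
from .timeseries import block_correlation_time

FORM_CUTOFF_NM = 0.38
BREAK_CUTOFF_NM = 0.8
MIN_SEQ_SEP = 4


@dataclass
class ContactEvent:
    chain_a: int
    res_a: int
    chain_b: int
    res_b: int
    formation_frame: int
    breaking_frame: int        # exclusive: first frame in the broken state
    lifetime_ns: float
    censored: bool = False     # open at either trajectory end

    def __post_init__(self) -> None:
        if self.breaking_frame < self.formation_frame:
            raise ValueError("breaking frame must be >= formation frame")


@dataclass
class ContactSummary:
    lifetimes_ns: np.ndarray
    mean_lifetime_ns: float
    mean_lifetime_se_ns: float
    bin_edges_ns: np.ndarray
    density: np.ndarray        # probability density per ns
    profile: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


def _residue_groups(frames: TrajectoryFrames, chain) -> list[tuple[int, int, np.ndarray]]:
    """(chain, resid, heavy-atom indices) per residue of one chain."""
    atoms = frames.atoms
    heavy = frames.heavy_mask()
    out = []
    sel = atoms[(atoms["chain"] == chain)]
    for resid, grp in sel.groupby("resid"):
        idx = grp.index.to_numpy()[heavy[grp.index.to_numpy()]]
        if idx.size:
            out.append((chain, int(resid), idx))
    return out


def _min_image(diff: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is not None:
        diff = diff - box * np.round(diff / box)
    return diff


def residue_min_distances(frames: TrajectoryFrames, chain_a, chain_b,
                          min_seq_sep: int = MIN_SEQ_SEP):
    """Minimum heavy-atom distance per residue pair per frame.

    Returns (distances (n_frames, n_pairs), pairs list of
    (chain_a, res_a, chain_b, res_b)). For intra-chain analysis
    (chain_a == chain_b) pairs closer than ``min_seq_sep`` in sequence
    are excluded; inter-chain pairs have no sequence separation.
    """
    ga = _residue_groups(frames, chain_a)
    gb = _residue_groups(frames, chain_b)
    intra = chain_a == chain_b
    pairs, pair_idx = [], []
    for ia, (ca, ra, idx_a) in enumerate(ga):
        for ib, (cb, rb, idx_b) in enumerate(gb):
            if intra and (ib <= ia or abs(ra - rb) < min_seq_sep):
                continue
            pairs.append((ca, ra, cb, rb))
            pair_idx.append((idx_a, idx_b))
    dists = np.empty((frames.n_frames, len(pairs)))
    for f in range(frames.n_frames):
        xyz = frames.coords[f]
        box = frames.box[f] if frames.box is not None else None
        for k, (idx_a, idx_b) in enumerate(pair_idx):
            diff = _min_image(xyz[idx_a][:, None, :] - xyz[idx_b][None, :, :], box)
            dists[f, k] = np.sqrt((diff ** 2).sum(axis=2)).min()
    return dists, pairs


def detect_contacts(frames: TrajectoryFrames, chain_a=0, chain_b=1,
                    form_cutoff: float = FORM_CUTOFF_NM,
                    break_cutoff: float = BREAK_CUTOFF_NM,
                    min_seq_sep: int = MIN_SEQ_SEP):
    """Dual-cutoff contact events plus the per-frame contact matrix.

    Returns (events, contact_matrix (n_frames, n_pairs) bool, pairs).
    The state machine is deterministic and independent of atom order:
    it only sees the per-pair minimum distances.
    """
    if break_cutoff <= form_cutoff:
        raise ValueError("break cutoff must exceed the formation cutoff")
    dists, pairs = residue_min_distances(frames, chain_a, chain_b, min_seq_sep)
    n_frames, n_pairs = dists.shape
    in_contact = np.zeros((n_frames, n_pairs), dtype=bool)
    state = dists[0] < form_cutoff
    in_contact[0] = state
    start = np.where(state, 0, -1)
    events: list[ContactEvent] = []
    dt_ns = frames.frame_interval * 1e-3
    for f in range(1, n_frames):
        form = (~state) & (dists[f] < form_cutoff)
        brk = state & (dists[f] > break_cutoff)
        for k in np.nonzero(brk)[0]:
            events.append(ContactEvent(*pairs[k], int(start[k]), f,
                                       (f - start[k]) * dt_ns,
                                       censored=start[k] == 0))
        state = (state | form) & ~brk
        start[form] = f
        in_contact[f] = state
    for k in np.nonzero(state)[0]:  # still formed at the last frame
        events.append(ContactEvent(*pairs[k], int(start[k]), n_frames,
                                   (n_frames - start[k]) * dt_ns, censored=True))
    return events, in_contact, pairs


def contact_lifetimes(events: list[ContactEvent], n_frames: int,
                      frame_interval_ps: float, censoring: str = "exclude",
                      bin_width_ns: float = 1.0, n_blocks: int = 10) -> ContactSummary:
    """Lifetime distribution and block-resampled mean lifetime.

    Events truncated by the trajectory ends are excluded by default
    (``censoring="include"`` keeps them). The mean's standard error
    comes from splitting the trajectory into temporal blocks by
    formation time.
    """
    if censoring not in ("exclude", "include"):
        raise ValueError("censoring must be 'exclude' or 'include'")
    kept = [e for e in events if censoring == "include" or not e.censored]
    if not kept:
        return ContactSummary(np.array([]), np.nan, np.nan,
                              np.array([0.0]), np.array([]),
                              meta={"empty": True, "n_events_total": len(events),
                                    "n_censored": sum(e.censored for e in events)})
    lt = np.array([e.lifetime_ns for e in kept])
    edges = np.arange(0.0, lt.max() + bin_width_ns, bin_width_ns)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width_ns])
    density, edges = np.histogram(lt, bins=edges, density=True)
    # block error: group events by formation-time block
    forms = np.array([e.formation_frame for e in kept])
    blocks = np.minimum(forms * n_blocks // max(n_frames, 1), n_blocks - 1)
    block_means = np.array([lt[blocks == b].mean()
                            for b in range(n_blocks) if (blocks == b).any()])
    se = block_means.std(ddof=0) / np.sqrt(len(block_means)) \
        if len(block_means) > 1 else np.nan
    return ContactSummary(lt, float(lt.mean()), float(se), edges, density,
                          meta={"censoring": censoring,
                                "n_censored": sum(e.censored for e in events)})


def residue_contact_profile(contact_matrix: np.ndarray, pairs,
                            chain: int = 0) -> pd.DataFrame:
    """Time-averaged number of simultaneous partner contacts per residue."""
    resids = sorted({p[1] if p[0] == chain else p[3]
                     for p in pairs if chain in (p[0], p[2])})
    counts = {r: np.zeros(contact_matrix.shape[0]) for r in resids}
    for k, (ca, ra, cb, rb) in enumerate(pairs):
        if ca == chain:
            counts[ra] += contact_matrix[:, k]
        if cb == chain and (ca != chain or rb != ra):
            counts[rb] += contact_matrix[:, k]
    return pd.DataFrame({"residue": resids,
                         "mean_contacts": [counts[r].mean() for r in resids]})


def count_bound_ligands(frames: TrajectoryFrames, chain_p: int,
                        ligand_chains, cutoff: float = 1.3,
                        stride_ps: float = 100.0):
    """Number of ligand chains within ``cutoff`` of the chain, over time.

    The minimum inter-chain heavy-atom distance is evaluated every
    ``stride_ps``. Returns (times_ns, counts, occupancy) where
    occupancy[i] is the fraction of evaluations with i ligands bound.
    """
    ligand_chains = list(ligand_chains)
    if not ligand_chains:
        raise ValueError("need at least one ligand chain")
    stride = max(int(round(stride_ps / frames.frame_interval)), 1)
    eval_frames = np.arange(0, frames.n_frames, stride)
    heavy = frames.heavy_mask()
    atoms = frames.atoms
    idx_p = atoms.index[(atoms["chain"] == chain_p)].to_numpy()
    idx_p = idx_p[heavy[idx_p]]
    counts = np.zeros(len(eval_frames), dtype=int)
    for j, f in enumerate(eval_frames):
        xyz = frames.coords[f]
        box = frames.box[f] if frames.box is not None else None
        for ch in ligand_chains:
            idx_l = atoms.index[(atoms["chain"] == ch)].to_numpy()
            idx_l = idx_l[heavy[idx_l]]
            diff = _min_image(xyz[idx_p][:, None, :] - xyz[idx_l][None, :, :], box)
            if np.sqrt((diff ** 2).sum(axis=2)).min() < cutoff:
                counts[j] += 1
    occupancy = np.bincount(counts, minlength=len(ligand_chains) + 1) / len(counts)
    times_ns = eval_frames * frames.frame_interval * 1e-3
    return times_ns, counts, occupancy


def radius_of_gyration(frames: TrajectoryFrames, chain=None) -> np.ndarray:
    """Mass-weighted radius of gyration per frame (nm)."""
    atoms = frames.atoms
    idx = atoms.index.to_numpy() if chain is None \
        else atoms.index[atoms["chain"] == chain].to_numpy()
    m = atom_masses(atoms.loc[idx])
    xyz = frames.coords[:, idx, :]
    com = (m[None, :, None] * xyz).sum(axis=1) / m.sum()
    d2 = ((xyz - com[:, None, :]) ** 2).sum(axis=2)
    return np.sqrt((m[None, :] * d2).sum(axis=1) / m.sum())


def rg_autocorrelation_time(series_or_frames, dt_ns: float | None = None,
                            chain=None, n_blocks: int = 10):
    """Integrated correlation time (ns) of Rg fluctuations, with block error.

    Accepts either a pre-computed scalar series (then ``dt_ns`` is
    required) or :class:`TrajectoryFrames` (mass-weighted Rg computed
    per frame). Warns when the series is shorter than ~20 estimated
    correlation times.
    """
    if isinstance(series_or_frames, TrajectoryFrames):
        x = radius_of_gyration(series_or_frames, chain=chain)
        dt_ns = series_or_frames.frame_interval * 1e-3
    else:
        x = np.asarray(series_or_frames, dtype=float)
        if dt_ns is None:
            raise ValueError("dt_ns required for a bare series")
    from .timeseries import integrated_correlation_time
    tau = integrated_correlation_time(x, dt_ns)
    _, se = block_correlation_time(x, dt_ns, n_blocks=n_blocks)
    if len(x) * dt_ns < 20 * tau:
        import warnings
        warnings.warn("series shorter than ~20 correlation times; "
                      "estimate may be unreliable", stacklevel=2)
    return tau, se
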