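"""Backtracking of per-frame colony observations into per-colony trajectories.

Microcolonies in a hydrogel particle only appear and expand in place — they do
not move — so the final frame is the most information-rich anchor.  Linking
therefore runs *backward*: each colony in frame ``t`` is matched to at most one
colony in an earlier frame by maximal pixel overlap, with a nearest-centroid
fallback for segmentation dropouts.  Matching is injective per frame pair;
when two later colonies contend for one ancestor (a split, going forward), the
larger overlap claims it and the loser's backtrack terminates, recorded as a
"split-orphan" in the QC output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import ColonyObservation


@dataclass
class ColonyTrack:
    """Time-ordered observations of one colony."""

    track_id: int
    birth_frame: int
    observations: list[ColonyObservation]
    final_distance_to_edge_um: float

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def times_h(self) -> np.ndarray:
        return np.array([o.time_h for o in self.observations])

    @property
    def areas_um2(self) -> np.ndarray:
        return np.array([o.area_um2 for o in self.observations])

    @property
    def median_o2_umol_L(self) -> np.ndarray:
        return np.array([o.median_o2_umol_L for o in self.observations])


@dataclass
class TrackingQC:
    split_orphans: list[tuple[int, int]] = field(default_factory=list)  # (frame, label)
    n_linked: int = 0
    n_centroid_fallback: int = 0


def resolve_overlap_conflicts(
    candidates: list[tuple[int, int, float, float, int]],
) -> tuple[dict[int, int], list[int]]:
    """Injective greedy assignment of later colonies to earlier ancestors.

    ``candidates`` are ``(tail_key, earlier_label, overlap, tail_area,
    tail_label)`` tuples.  Sorted by descending overlap, then descending tail
    area, then ascending tail label — a deterministic order independent of the
    input sequence.  Returns ``(assignment: tail_key -> earlier_label,
    orphans: tail_keys that lost every ancestor they overlapped)``.
    """
    order = sorted(candidates, key=lambda x: (-x[2], -x[3], x[4]))
    assigned: dict[int, int] = {}
    claimed: set[int] = set()
    contenders: dict[int, set[int]] = {}
    for tail, earlier, _ov, _area, _lab in order:
        contenders.setdefault(tail, set()).add(earlier)
        if tail in assigned or earlier in claimed:
            continue
        assigned[tail] = earlier
        claimed.add(earlier)
    orphans = [t for t, opts in contenders.items()
               if t not in assigned and opts <= claimed]
    return assigned, orphans


def _overlap_counts(later: np.ndarray, earlier: np.ndarray) -> dict[tuple[int, int], int]:
    """Pixel overlap between every (later label, earlier label) pair."""
    sel = (later > 0) & (earlier > 0)
    if not sel.any():
        return {}
    pairs = np.stack([later[sel], earlier[sel]])
    uniq, counts = np.unique(pairs, axis=1, return_counts=True)
    return {(int(a), int(b)): int(n) for (a, b), n in zip(uniq.T, counts)}


def backtrack(
    label_stack: np.ndarray | list[np.ndarray],
    observations_by_frame: list[list[ColonyObservation]],
    max_gap: int = 2,
    max_link_distance_um: float = 20.0,
    pixel_size_um: float = 1.0,
) -> tuple[list[ColonyTrack], TrackingQC]:
    """Link per-frame observations into tracks, starting at the last frame.

    ``label_stack`` holds the per-frame colony label maps produced by
    segmentation; ``observations_by_frame[i]`` the matching observations.
    A track may skip up to ``max_gap`` consecutive frames (transient
    segmentation dropouts).  Empty input yields an empty list.
    """
    n_frames = len(observations_by_frame)
    if n_frames == 0:
        return [], TrackingQC()
    labels = [np.asarray(label_stack[i]) for i in range(n_frames)]
    obs_lookup = [
        {o.label: o for o in frame_obs} for frame_obs in observations_by_frame
    ]

    qc = TrackingQC()
    # Tracks under construction: id -> list of observations (reverse time order).
    chains: dict[int, list[ColonyObservation]] = {}
    # Open tails: track id -> (frame of earliest obs, label at that frame).
    tails: dict[int, tuple[int, int]] = {}
    next_id = 0
    for o in sorted(observations_by_frame[-1], key=lambda o: o.label):
        chains[next_id] = [o]
        tails[next_id] = (n_frames - 1, o.label)
        next_id += 1

    for t in range(n_frames - 2, -1, -1):
        earlier = labels[t]
        available = {o.label for o in observations_by_frame[t]}
        # Tails still allowed to bridge down to frame t (gap constraint).
        eligible = {
            tid: (f0, lab) for tid, (f0, lab) in tails.items()
            if f0 - t - 1 <= max_gap
        }
        candidates = []
        for tid, (f0, lab) in eligible.items():
            tail_mask = labels[f0] == lab
            area = obs_lookup[f0][lab].area_um2
            counts = _overlap_counts(np.where(tail_mask, lab, 0), earlier)
            for (_, elab), n in counts.items():
                if elab in available:
                    candidates.append((tid, elab, float(n), area, lab))
        assigned, orphans = resolve_overlap_conflicts(candidates)

        # Centroid fallback for eligible tails with no overlap assignment.
        claimed = set(assigned.values())
        for tid in sorted(eligible):
            if tid in assigned or tid in orphans:
                continue
            f0, lab = eligible[tid]
            cy, cx = obs_lookup[f0][lab].centroid
            best, best_d = None, np.inf
            for elab in sorted(available - claimed):
                ey, ex = obs_lookup[t][elab].centroid
                d = np.hypot(cy - ey, cx - ex) * pixel_size_um
                if d < best_d:
                    best, best_d = elab, d
            if best is not None and best_d <= max_link_distance_um:
                assigned[tid] = best
                claimed.add(best)
                qc.n_centroid_fallback += 1

        for tid in orphans:
            f0, lab = eligible[tid]
            qc.split_orphans.append((f0, lab))
        # Extend assigned tracks; orphaned or unmatched tails close silently
        # (their colony was born at its earliest observed frame).
        for tid, elab in sorted(assigned.items()):
            chains[tid].append(obs_lookup[t][elab])
            tails[tid] = (t, elab)
            qc.n_linked += 1
        # Orphans and gap-expired tails stop being eligible naturally; remove
        # orphans explicitly so they never match again.
        for tid in orphans:
            tails.pop(tid, None)
        # Earlier-frame colonies nobody claimed start their own tracks.
        for elab in sorted(available - set(assigned.values())):
            chains[next_id] = [obs_lookup[t][elab]]
            tails[next_id] = (t, elab)
            next_id += 1

    tracks = []
    for tid in sorted(chains):
        obs = list(reversed(chains[tid]))
        tracks.append(
            ColonyTrack(
                track_id=tid,
                birth_frame=obs[0].frame_index,
                observations=obs,
                final_distance_to_edge_um=obs[-1].distance_to_edge_um,
            )
        )
    return tracks, qc
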