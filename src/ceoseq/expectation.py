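"""Closed-form expected coverage and enrichment fold for the protocol model.

Derivation (matches the sampling model in :mod:`ceoseq.protocol`):

* Fragmentation is an equilibrium (stationary-phase) renewal process
  with i.i.d. uniform(f_lo, f_hi) fragment lengths over the genome
  window of length G, so interior shear boundaries have uniform
  density 1/E[F] and the expected boundary count is G/E[F]. Each
  interior boundary carries two pre-existing ends (the window's outer
  coordinates are continuations of the larger genome and never
  ligate), each ligatable with probability p_bg — escape of
  dephosphorylation plus the background re-ligation rate — and each
  ligatable end seeds a read with probability r.

* A read of length L (lognormal with a hard floor, the simulator's
  model) from an end deposits bases until the first blocking event:
  its own length, the next shear boundary, or the next guide cut that
  fired. The expected bases deposited at travel distances [a, b) are

      integral_a^b  S_L(u) * S_B(u) * C(u)  du

  where S_L is the read-length survival, S_B the survival of the
  distance to the next shear boundary (a full fragment length from a
  pre-existing boundary end; the stationary residual-life distribution
  from a cut, which sits at an arbitrary phase of the shear process),
  and C(u) the probability that no intervening guide cut within
  distance u fired (product of 1 - cut_efficiency over cuts passed).

* Each fired cut contributes two fresh ligatable ends (left- and
  right-running); expected genome-wide depth is total deposited bases
  over G, expected target depth is background depth plus each cut
  end's expected overlap with the target interval divided by the
  target length. The enrichment fold is their ratio (the number of
  genome copies cancels).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .locus import SyntheticLocus
from .protocol import ProtocolParams, guide_cut_coords

_GRID_STEP = 50.0


class _Blocking:
    """Numerical expectation machinery for one parameter set."""

    def __init__(self, params: ProtocolParams) -> None:
        flo, fhi = params.fragment_len_range
        self.fbar = (flo + fhi) / 2.0
        self.u = np.arange(0.0, fhi + _GRID_STEP, _GRID_STEP)
        d = stats.lognorm(s=params.read_len_sigma, scale=params.read_len_median)
        # survival of read length with hard floor: S(u) = 1 for u < floor
        self.s_len = np.where(self.u < params.read_len_min, 1.0, d.sf(self.u))
        # full fragment-length survival (uniform)
        self.s_frag = np.clip((fhi - self.u) / (fhi - flo), 0.0, 1.0)
        self.s_frag[self.u < flo] = 1.0
        # stationary residual-life survival: S_R(u) = int_u^inf S_F / E[F]
        tail = np.concatenate([
            (np.cumsum(self.s_frag[::-1]) * _GRID_STEP)[::-1][1:], [0.0],
        ])
        self.s_resid = tail / self.fbar

    def bases(self, s_block: np.ndarray, cut_factor: np.ndarray,
              a: float = 0.0, b: float = np.inf) -> float:
        """integral_a^b S_L * s_block * cut_factor du (trapezoid)."""
        mask = (self.u >= a) & (self.u <= min(b, self.u[-1]))
        if mask.sum() < 2:
            return 0.0
        integrand = self.s_len * s_block * cut_factor
        return float(np.trapezoid(integrand[mask], self.u[mask]))

    def cut_survival(self, distances_effs: list[tuple[float, float]]) -> np.ndarray:
        """C(u): probability no intervening cut within distance u fired."""
        c = np.ones_like(self.u)
        for dist, eff in distances_effs:
            c[self.u > dist] *= 1.0 - eff
        return c


def expected_enrichment_fold(locus: SyntheticLocus, params: ProtocolParams) -> float:
    """Closed-form expectation of the target region's enrichment fold."""
    G = float(locus.spec.genome_len)
    r = params.reads_per_ligatable_end
    bl = _Blocking(params)
    ones = np.ones_like(bl.u)

    # background: two ends per interior boundary, boundary count G/E[F];
    # a background read is capped one full fragment away
    n_bg_reads = 2.0 * (G / bl.fbar) * params.ligatable_end_prob * r
    bg_bases = n_bg_reads * bl.bases(bl.s_frag, ones)

    cuts = sorted(
        (guide_cut_coords(g, params.cut_offsets), params.efficiency_of(g.name))
        for g in locus.guides
    )
    t0, t1 = (float(x) for x in locus.regions.target.interval0())

    cut_bases = 0.0
    target_cut_bases = 0.0
    for idx, ((cut_lo, cut_hi), eff) in enumerate(cuts):
        for direction, p in ((+1, float(cut_lo)), (-1, float(cut_hi))):
            if direction > 0:
                beyond = [(float(c[0][1]) - p, c[1]) for c in cuts[idx + 1 :]]
                a, b = max(t0 - p, 0.0), max(t1 - p, 0.0)
            else:
                beyond = [(p - float(c[0][0]), c[1]) for c in reversed(cuts[:idx])]
                a, b = max(p - t1, 0.0), max(p - t0, 0.0)
            c_surv = bl.cut_survival(beyond)
            weight = eff * r
            cut_bases += weight * bl.bases(bl.s_resid, c_surv)
            if b > a:
                target_cut_bases += weight * bl.bases(bl.s_resid, c_surv, a, b)

    genome_depth = (bg_bases + cut_bases) / G
    target_depth = bg_bases / G + target_cut_bases / (t1 - t0)
    return target_depth / genome_depth
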