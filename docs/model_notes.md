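# Modelling notes and deliberate deviations

## Repressor-chain balance

The repressor-complex balance in the transcription chain is implemented as

    dR/dt = alpha3 * r - beta3 * R

(production from the repressor protein `r`, first-order removal).  A
literal transcription of the source material's display would read
`dR/dt = alpha3*R - beta3*R`, which decouples `R` from `r` and `M` and
admits no feedback; the implemented form matches the verbal description of
the mechanism (repressor protein forms the final complex) and the
structure of the other chain models.

## Transcription-coupled model constants

The fold factor 100 and Hill exponent 4 in the S-inhibited transcription
term are structural constants of the model, not free parameters.

## Stand-in sampling ranges

The fixed rates and sampling bounds in `data/standin_ranges.yaml` are
package calibrations standing in for an unavailable reference table.  They
were chosen (see `scripts/calibrate_detailed.py` and the ranges file
comments) so that:

* the three-phosphoform model has a non-trivial oscillating region at
  `Kd = 1e-4` with a ~24 h median period, and its oscillating sets respect
  the strict stoichiometric condition `C_T > 3 A_T`;
* the paired transcription-mode comparison lands near the expected
  oscillating fractions (~99% vs ~60%).

They are deliberately overridable from a user config.

## Stoichiometric condition constant

The condition is `C_T > (1 + r) A_T + eps` with `r` a rate-related
constant.  The package exposes `r_const` as a free constant defaulting to
2 (so the working criterion is `C_T > 3 A_T`, strict inequality at the
boundary), with `eps = 0` by default.

## Detailed-cycle calibration targets

The detailed-cycle rate defaults are calibrated, not measured.  The
calibration targets a circadian period with a 9.5 h phosphorylation
(rising) phase.  Note that the trough-to-peak and peak-to-trough durations
of a periodic signal must sum to its period, so a 9.5 h + 18.5 h phase
split is arithmetically incompatible with a 24 h period; the calibration
resolves this in favour of the period and the rising-phase duration
(baseline: period 24.6 h, tau1 = 9.5 h, tau2 = 15.1 h).  The
dephosphorylation phase remains the longer one, preserving the qualitative
asymmetry.

## ATP/ADP dependence

The ATP/(ATP+ADP) ratio enters as a multiplicative scale on the
KaiA-stimulated phosphorylation rate — the simplest mass-action entry
point for nucleotide dependence.  The calibrated cycle keeps its period
within 1% over the ratio grid {1.0, 0.85, 0.7, 0.55} and stops
oscillating below ~0.5, so that grid is what "spanning the oscillatory
range" means for this reconstruction.

## Oscillation-detector thresholds

The spectral criterion (transient cut 30%, dominant nonzero-frequency peak
with relative amplitude >= 1% of the series mean and >= 5x the median
spectral amplitude) is a package decision; the event-location criterion
(last three mean-upcrossing gaps equal within 1e-3 time units) is
implemented verbatim.  Random initial states for the event procedure are
drawn uniformly from (0, 10] per state from the run's seeded substream.
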