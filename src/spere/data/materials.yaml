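# Materials registry: dispersion model + coefficients + validated range.
#
# Models:
#   sellmeier:  n^2 = 1 + sum_i B_i * L^2 / (L^2 - C_i),  L = wavelength in um
#   cauchy:     n   = A + B / L^2 + C / L^4,              L = wavelength in um
#   constant:   n   = value (non-dispersive)
#
# Sources (standard literature fits, visible band):
#   polystyrene  Sultanova, Kasarova & Nikolov (2009), one-term Sellmeier.
#                Fit measured over 436.8-1052 nm; the lower bound here extends
#                to 400 nm by smooth extrapolation of the Sellmeier form so
#                the full 400-700 nm simulation band is usable.
#   water        Daimon & Masumura (2007), 20 C, four-term Sellmeier.
#   fused_silica Malitson (1965), three-term Sellmeier.
#   Non-dispersive entries are single published values (protein adlayer,
#   PDMS, 5CB liquid-crystal principal indices).
version: 1
materials:
  polystyrene:
    model: sellmeier
    B: [1.4435]
    C: [0.020216]
    valid_range_nm: [400.0, 1052.0]
  water:
    model: sellmeier
    B: [5.684027565e-1, 1.726177391e-1, 2.086189578e-2, 1.130748688e-1]
    C: [5.101829712e-3, 1.821153936e-2, 2.620722293e-2, 1.069792721e1]
    valid_range_nm: [380.0, 1100.0]
  fused_silica:
    model: sellmeier
    B: [0.6961663, 0.4079426, 0.8974794]
    C: [0.004679148, 0.013512063, 97.93400254]
    valid_range_nm: [250.0, 2300.0]
  silica:
    alias: fused_silica
  streptavidin_layer:
    model: constant
    n: 1.50
    valid_range_nm: [300.0, 1500.0]
  pdms:
    model: constant
    n: 1.41
    valid_range_nm: [300.0, 1500.0]
  lc_5cb_ordinary:
    model: constant
    n: 1.55
    valid_range_nm: [300.0, 1500.0]
  lc_5cb_extraordinary:
    model: constant
    n: 1.74
    valid_range_nm: [300.0, 1500.0]
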