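# Reference spectral response matrix (version 1).
#
# Rows: one fluorophore per epitope slot, in slot order.
# Columns: the 10 excitation/emission frames of the default acquisition
# scheme (brightfield excluded).  Entries are expected detected intensity
# per unit fluorophore abundance, in arbitrary units, with each row scaled
# so that its matched excitation/emission frame equals 1.0.  Off-frame
# entries model emission tails and cross-excitation (bleed-through).
version: 1
fluorophores: [DyLight405, Atto488, Atto565, Star635P]
epitope_slots: ["mCherry(Y71L)", "GFP(Y66L)", syn87, syn2]
channels:
  ["405/CH1", "405/CH2", "405/CH3", "405/CH4",
   "488/CH2", "488/CH3", "488/CH4",
   "561/CH3", "561/CH4",
   "633/CH4"]
response:
  DyLight405: [1.00, 0.25, 0.05, 0.02, 0.04, 0.02, 0.00, 0.00, 0.00, 0.00]
  Atto488:    [0.00, 0.12, 0.03, 0.00, 1.00, 0.22, 0.04, 0.03, 0.00, 0.00]
  Atto565:    [0.00, 0.00, 0.03, 0.00, 0.00, 0.15, 0.04, 1.00, 0.20, 0.02]
  Star635P:   [0.00, 0.00, 0.00, 0.02, 0.00, 0.00, 0.05, 0.02, 0.18, 1.00]
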