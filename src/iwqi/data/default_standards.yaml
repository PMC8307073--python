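# Default per-parameter standards for quality-rating and exceedance reporting.
#
# T        : standard (permissible) value, same units as measurements
# C_ideal  : ideal value in pure water (0 everywhere except pH, where 7)
# limit    : exceedance threshold used for %SES reporting
#
# TH, HCO3, Fe and NO3_N carry the drinking-water limits used in the source
# assessment; TDS, Cl, SO4, Na, F and NO2_N are Chinese Class-III groundwater
# values; Ca, Mg and K are placeholder limits (no statutory Class-III value)
# and should be overridden where a local standard exists.
pH:    {T: 8.5,    C_ideal: 7.0, limit: 8.5}
TDS:   {T: 1000.0, C_ideal: 0.0, limit: 1000.0}
TH:    {T: 450.0,  C_ideal: 0.0, limit: 450.0}
Ca:    {T: 200.0,  C_ideal: 0.0, limit: 200.0}
Na:    {T: 200.0,  C_ideal: 0.0, limit: 200.0}
Mg:    {T: 150.0,  C_ideal: 0.0, limit: 150.0}
K:     {T: 12.0,   C_ideal: 0.0, limit: 12.0}
Fe:    {T: 0.3,    C_ideal: 0.0, limit: 0.3}
HCO3:  {T: 250.0,  C_ideal: 0.0, limit: 250.0}
SO4:   {T: 250.0,  C_ideal: 0.0, limit: 250.0}
Cl:    {T: 250.0,  C_ideal: 0.0, limit: 250.0}
NO3_N: {T: 20.0,   C_ideal: 0.0, limit: 20.0}
F:     {T: 1.0,    C_ideal: 0.0, limit: 1.0}
NO2_N: {T: 1.0,    C_ideal: 0.0, limit: 1.0}
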