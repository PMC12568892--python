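# Accepted physiological ("usable") ranges per biomarker.  Values outside
# a range indicate a segmentation or measurement failure and are flagged,
# never censored.  Boundaries are inclusive.
muscle_csa:        {low: 25.0,   high: 500.0,   units: cm2}
muscle_density:    {low: -50.0,  high: 200.0,   units: HU}
abdominal_agatston: {low: 0.0,   high: 40000.0, units: unitless}
total_agatston:    {low: 0.0,    high: 40000.0, units: unitless}
trabecular_density: {low: -50.0, high: 1200.0,  units: HU}
vat_csa:           {low: 0.0,    high: 1200.0,  units: cm2}
sat_csa:           {low: 0.1,    high: 1000.0,  units: cm2}
total_fat_csa:     {low: 0.1,    high: 1500.0,  units: cm2}
vsr:               {low: 0.02,   high: 10.0,    units: unitless}
vat_density:       {low: -120.0, high: -60.0,   units: HU}
sat_density:       {low: -120.0, high: -30.0,   units: HU}
liver_density:     {low: -50.0,  high: 180.0,   units: HU}
liver_volume:      {low: 100.0,  high: 5000.0,  units: mL}
spleen_density:    {low: 10.0,   high: 500.0,   units: HU}
spleen_volume:     {low: 50.0,   high: 6000.0,  units: mL}
kidney_density:    {low: 5.0,    high: 300.0,   units: HU}
kidney_volume:     {low: 50.0,   high: 750.0,   units: mL}
pancreas_density:  {low: -10.0,  high: 260.0,   units: HU}
pancreas_volume:   {low: 20.0,   high: 140.0,   units: mL}
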