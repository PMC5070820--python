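{
  "description": "Published ActiGraph intensity cut points (cpm) calibrated in typically developing children, for comparison with newly calibrated sets. Null marks a boundary the study did not report (e.g. MVPA-only calibrations). 'sedentary_upper_includes_light' flags sets whose lowest band pools sedentary and light intensity.",
  "references": [
    {"study": "Puyau", "year": 2002, "axis": "vertical", "sedentary_upper": 799, "moderate_lower": 3200, "moderate_upper": 8199, "vigorous_lower": 8200, "mvpa_lower": null, "sedentary_upper_includes_light": false},
    {"study": "Treuth", "year": 2004, "axis": "vertical", "sedentary_upper": 100, "moderate_lower": 3000, "moderate_upper": 5200, "vigorous_lower": 5201, "mvpa_lower": null, "sedentary_upper_includes_light": false},
    {"study": "Freedson", "year": 2005, "axis": "vertical", "sedentary_upper": 500, "moderate_lower": 501, "moderate_upper": 4000, "vigorous_lower": 4001, "mvpa_lower": null, "sedentary_upper_includes_light": true},
    {"study": "Mattocks", "year": 2007, "axis": "vertical", "sedentary_upper": 100, "moderate_lower": 3581, "moderate_upper": 6129, "vigorous_lower": 6130, "mvpa_lower": null, "sedentary_upper_includes_light": false},
    {"study": "Evenson", "year": 2008, "axis": "vertical", "sedentary_upper": 100, "moderate_lower": 2296, "moderate_upper": 4011, "vigorous_lower": 4012, "mvpa_lower": null, "sedentary_upper_includes_light": false},
    {"study": "Pulsford", "year": 2011, "axis": "vertical", "sedentary_upper": 99, "moderate_lower": 2241, "moderate_upper": 3840, "vigorous_lower": 3841, "mvpa_lower": null, "sedentary_upper_includes_light": false},
    {"study": "Vanhelst", "year": 2011, "axis": "vertical", "sedentary_upper": 400, "moderate_lower": 1901, "moderate_upper": 3918, "vigorous_lower": 3919, "mvpa_lower": null, "sedentary_upper_includes_light": false},
    {"study": "Mackintosh", "year": 2012, "axis": "vertical", "sedentary_upper": 372, "moderate_lower": 2161, "moderate_upper": 4806, "vigorous_lower": 4807, "mvpa_lower": null, "sedentary_upper_includes_light": false},
    {"study": "Jimmy", "year": 2013, "axis": "vertical", "sedentary_upper": null, "moderate_lower": 1596, "moderate_upper": 2315, "vigorous_lower": 2316, "mvpa_lower": null, "sedentary_upper_includes_light": false},
    {"study": "Romanzini", "year": 2014, "axis": "vertical", "sedentary_upper": 184, "moderate_lower": 2428, "moderate_upper": 3271, "vigorous_lower": 3272, "mvpa_lower": null, "sedentary_upper_includes_light": false},
    {"study": "Current study", "year": 2016, "axis": "vertical", "sedentary_upper": 507, "moderate_lower": 1008, "moderate_upper": 2300, "vigorous_lower": 2301, "mvpa_lower": 1008, "sedentary_upper_includes_light": false},
    {"study": "Santos-Lozano", "year": 2013, "axis": "vm", "sedentary_upper": 2114, "moderate_lower": 2114, "moderate_upper": 6547, "vigorous_lower": 6548, "mvpa_lower": null, "sedentary_upper_includes_light": true},
    {"study": "Hanggi", "year": 2013, "axis": "vm", "sedentary_upper": 180, "moderate_lower": null, "moderate_upper": null, "vigorous_lower": null, "mvpa_lower": 3361, "sedentary_upper_includes_light": false},
    {"study": "Jimmy", "year": 2013, "axis": "vm", "sedentary_upper": null, "moderate_lower": 2952, "moderate_upper": 3791, "vigorous_lower": 3792, "mvpa_lower": null, "sedentary_upper_includes_light": false},
    {"study": "Romanzini", "year": 2014, "axis": "vm", "sedentary_upper": 720, "moderate_lower": 3028, "moderate_upper": 4447, "vigorous_lower": 4448, "mvpa_lower": null, "sedentary_upper_includes_light": false},
    {"study": "Current study", "year": 2016, "axis": "vm", "sedentary_upper": 1863, "moderate_lower": 2610, "moderate_upper": 4214, "vigorous_lower": 4215, "mvpa_lower": 2610, "sedentary_upper_includes_light": false}
  ]
}
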