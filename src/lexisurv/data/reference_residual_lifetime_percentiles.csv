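entry_age,percentile,grade,sex,age_at_death
25,0.05,never,male,54.92
25,0.05,never,female,59.50
25,0.05,light,male,52.33
25,0.05,light,female,53.33
25,0.05,medium,male,49.08
25,0.05,medium,female,51.67
25,0.05,heavy,male,47.08
25,0.05,heavy,female,51.42
25,0.50,never,male,82.83
25,0.50,never,female,85.83
25,0.50,light,male,80.75
25,0.50,light,female,81.33
25,0.50,medium,male,77.17
25,0.50,medium,female,80.17
25,0.50,heavy,male,75.50
25,0.50,heavy,female,80.00
25,0.95,never,male,100.50
25,0.95,never,female,103.92
25,0.95,light,male,96.33
25,0.95,light,female,94.08
25,0.95,medium,male,91.25
25,0.95,medium,female,92.08
25,0.95,heavy,male,89.17
25,0.95,heavy,female,91.83
45,0.05,never,male,55.25
45,0.05,never,female,58.92
45,0.05,light,male,54.00
45,0.05,light,female,55.00
45,0.05,medium,male,52.00
45,0.05,medium,female,53.92
45,0.05,heavy,male,51.17
45,0.05,heavy,female,90.50
45,0.50,never,male,78.50
45,0.50,never,female,84.33
45,0.50,light,male,75.92
45,0.50,light,female,78.42
45,0.50,medium,male,72.08
45,0.50,medium,female,76.75
45,0.50,heavy,male,70.33
45,0.50,heavy,female,76.50
45,0.95,never,male,98.00
45,0.95,never,female,102.58
45,0.95,light,male,93.75
45,0.95,light,female,92.75
45,0.95,medium,male,88.67
45,0.95,medium,female,90.83
45,0.95,heavy,male,86.58
45,0.95,heavy,female,53.75
65,0.05,never,male,66.75
65,0.05,never,female,68.42
65,0.05,light,male,66.62
65,0.05,light,female,67.00
65,0.05,medium,male,66.00
65,0.05,medium,female,66.75
65,0.05,heavy,male,65.83
65,0.05,heavy,female,66.75
65,0.50,never,male,78.58
65,0.50,never,female,83.33
65,0.50,light,male,76.75
65,0.50,light,female,79.08
65,0.50,medium,male,74.58
65,0.50,medium,female,77.75
65,0.50,heavy,male,73.33
65,0.50,heavy,female,77.58
65,0.95,never,male,94.00
65,0.95,never,female,100.08
65,0.95,light,male,90.58
65,0.95,light,female,91.25
65,0.95,medium,male,86.58
65,0.95,medium,female,89.50
65,0.95,heavy,male,85.17
65,0.95,heavy,female,89.25
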