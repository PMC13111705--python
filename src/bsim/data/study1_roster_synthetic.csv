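id,study,n_human_A,n_human_S,n_ai_A,n_ai_S,pi_direction,acc_human,acc_ai,acc_pi,posterior_A
S1-001,1,0,0,1,0,A,,0.66666666666666663,0.66666666666666663,0.800000
S1-002,1,0,0,1,0,S,,0.66666666666666663,0.66666666666666663,0.500000
S1-003,1,0,0,0,1,A,,0.66666666666666663,0.66666666666666663,0.500000
S1-004,1,0,0,0,1,S,,0.66666666666666663,0.66666666666666663,0.200000
S1-005,1,1,0,0,0,A,0.66666666666666663,,0.66666666666666663,0.800000
S1-006,1,1,0,0,0,S,0.66666666666666663,,0.66666666666666663,0.500000
S1-007,1,0,1,0,0,A,0.66666666666666663,,0.66666666666666663,0.500000
S1-008,1,0,1,0,0,S,0.66666666666666663,,0.66666666666666663,0.200000
S1-009,1,0,0,2,0,A,,0.66666666666666663,0.66666666666666663,0.888889
S1-010,1,0,0,2,0,S,,0.66666666666666663,0.66666666666666663,0.666667
S1-011,1,0,0,1,1,A,,0.66666666666666663,0.66666666666666663,0.666667
S1-012,1,0,0,1,1,S,,0.66666666666666663,0.66666666666666663,0.333333
S1-013,1,1,0,1,0,A,0.66666666666666663,0.66666666666666663,0.66666666666666663,0.888889
S1-014,1,1,0,1,0,S,0.66666666666666663,0.66666666666666663,0.66666666666666663,0.666667
S1-015,1,0,1,1,0,A,0.66666666666666663,0.66666666666666663,0.66666666666666663,0.666667
S1-016,1,0,1,1,0,S,0.66666666666666663,0.66666666666666663,0.66666666666666663,0.333333
S1-017,1,0,0,0,2,A,,0.66666666666666663,0.66666666666666663,0.333333
S1-018,1,0,0,0,2,S,,0.66666666666666663,0.66666666666666663,0.111111
S1-019,1,1,0,0,1,A,0.66666666666666663,0.66666666666666663,0.66666666666666663,0.666667
S1-020,1,1,0,0,1,S,0.66666666666666663,0.66666666666666663,0.66666666666666663,0.333333
S1-021,1,0,1,0,1,A,0.66666666666666663,0.66666666666666663,0.66666666666666663,0.333333
S1-022,1,0,1,0,1,S,0.66666666666666663,0.66666666666666663,0.66666666666666663,0.111111
S1-023,1,2,0,0,0,A,0.66666666666666663,,0.66666666666666663,0.888889
S1-024,1,2,0,0,0,S,0.66666666666666663,,0.66666666666666663,0.666667
S1-025,1,1,1,0,0,A,0.66666666666666663,,0.66666666666666663,0.666667
S1-026,1,1,1,0,0,S,0.66666666666666663,,0.66666666666666663,0.333333
S1-027,1,0,2,0,0,A,0.66666666666666663,,0.66666666666666663,0.333333
S1-028,1,0,2,0,0,S,0.66666666666666663,,0.66666666666666663,0.111111
S1-029,1,0,0,2,1,A,,0.66666666666666663,0.66666666666666663,0.800000
S1-030,1,0,0,2,1,S,,0.66666666666666663,0.66666666666666663,0.500000
S1-031,1,0,1,2,0,A,0.66666666666666663,0.66666666666666663,0.66666666666666663,0.800000
S1-032,1,0,1,2,0,S,0.66666666666666663,0.66666666666666663,0.66666666666666663,0.500000
S1-033,1,0,0,1,2,A,,0.66666666666666663,0.66666666666666663,0.500000
S1-034,1,0,0,1,2,S,,0.66666666666666663,0.66666666666666663,0.200000
S1-035,1,1,0,1,1,A,0.66666666666666663,0.66666666666666663,0.66666666666666663,0.800000
S1-036,1,1,0,1,1,S,0.66666666666666663,0.66666666666666663,0.66666666666666663,0.500000
S1-037,1,0,1,1,1,A,0.66666666666666663,0.66666666666666663,0.66666666666666663,0.500000
S1-038,1,0,1,1,1,S,0.66666666666666663,0.66666666666666663,0.66666666666666663,0.200000
S1-039,1,1,1,1,0,A,0.66666666666666663,0.66666666666666663,0.66666666666666663,0.800000
S1-040,1,1,1,1,0,S,0.66666666666666663,0.66666666666666663,0.66666666666666663,0.500000
S1-041,1,0,2,1,0,A,0.66666666666666663,0.66666666666666663,0.66666666666666663,0.500000
S1-042,1,0,2,1,0,S,0.66666666666666663,0.66666666666666663,0.66666666666666663,0.200000
S1-043,1,1,0,0,2,A,0.66666666666666663,0.66666666666666663,0.66666666666666663,0.500000
S1-044,1,1,0,0,2,S,0.66666666666666663,0.66666666666666663,0.66666666666666663,0.200000
S1-045,1,2,0,0,1,A,0.66666666666666663,0.66666666666666663,0.66666666666666663,0.800000
S1-046,1,2,0,0,1,S,0.66666666666666663,0.66666666666666663,0.66666666666666663,0.500000
S1-047,1,1,1,0,1,A,0.66666666666666663,0.66666666666666663,0.66666666666666663,0.500000
S1-048,1,1,1,0,1,S,0.66666666666666663,0.66666666666666663,0.66666666666666663,0.200000
S1-049,1,2,1,0,0,A,0.66666666666666663,,0.66666666666666663,0.800000
S1-050,1,2,1,0,0,S,0.66666666666666663,,0.66666666666666663,0.500000
S1-051,1,1,2,0,0,A,0.66666666666666663,,0.66666666666666663,0.500000
S1-052,1,1,2,0,0,S,0.66666666666666663,,0.66666666666666663,0.200000
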