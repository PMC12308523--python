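case_id,t1,t3,a_alive_later,b_alive_later,juv,expected_status
c001,together,together,0,0,none,faithful
c002,together,together,0,1,none,faithful
c003,together,together,1,0,none,faithful
c004,together,together,1,1,none,faithful
c005,together,both_others,0,0,none,divorcing
c006,together,both_others,0,1,none,divorcing
c007,together,both_others,1,0,none,divorcing
c008,together,both_others,1,1,none,divorcing
c009,together,A_other_B_none,0,0,none,excluded_unclear
c010,together,A_other_B_none,0,1,none,divorcing
c011,together,A_other_B_none,1,0,none,excluded_unclear
c012,together,A_other_B_none,1,1,none,divorcing
c013,together,B_other_A_none,0,0,none,excluded_unclear
c014,together,B_other_A_none,0,1,none,excluded_unclear
c015,together,B_other_A_none,1,0,none,divorcing
c016,together,B_other_A_none,1,1,none,divorcing
c017,together,none,0,0,none,excluded_unclear
c018,together,none,0,1,none,excluded_unclear
c019,together,none,1,0,none,excluded_unclear
c020,together,none,1,1,none,excluded_unclear
c021,both_others,together,0,0,none,new
c022,both_others,together,0,1,none,new
c023,both_others,together,1,0,none,new
c024,both_others,together,1,1,none,new
c025,A_other_B_none,together,0,0,none,excluded_unclear
c026,A_other_B_none,together,0,1,none,excluded_unclear
c027,A_other_B_none,together,1,0,none,excluded_unclear
c028,A_other_B_none,together,1,1,none,excluded_unclear
c029,A_other_B_none,together,0,0,B,new
c030,A_other_B_none,together,0,1,B,new
c031,A_other_B_none,together,1,0,B,new
c032,A_other_B_none,together,1,1,B,new
c033,B_other_A_none,together,0,0,none,excluded_unclear
c034,B_other_A_none,together,0,1,none,excluded_unclear
c035,B_other_A_none,together,1,0,none,excluded_unclear
c036,B_other_A_none,together,1,1,none,excluded_unclear
c037,B_other_A_none,together,0,0,A,new
c038,B_other_A_none,together,0,1,A,new
c039,B_other_A_none,together,1,0,A,new
c040,B_other_A_none,together,1,1,A,new
c041,none,together,0,0,none,excluded_unclear
c042,none,together,0,1,none,excluded_unclear
c043,none,together,1,0,none,excluded_unclear
c044,none,together,1,1,none,excluded_unclear
c045,none,together,0,0,A,excluded_unclear
c046,none,together,0,1,A,excluded_unclear
c047,none,together,1,0,A,excluded_unclear
c048,none,together,1,1,A,excluded_unclear
c049,none,together,0,0,B,excluded_unclear
c050,none,together,0,1,B,excluded_unclear
c051,none,together,1,0,B,excluded_unclear
c052,none,together,1,1,B,excluded_unclear
c053,none,together,0,0,both,juvenile
c054,none,together,0,1,both,juvenile
c055,none,together,1,0,both,juvenile
c056,none,together,1,1,both,juvenile
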