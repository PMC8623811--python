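family	domain_name	category	start	end
CHD1	Helicase ATP-binding	Helicases	493	663
CHD3	Helicase ATP-binding	Helicases	748	932
CHD3	Helicase C-terminal	Helicases	1064	1229
CHD4	Helicase ATP-binding	Helicases	738	922
CHD4	Helicase C-terminal	Helicases	1054	1203
CHD7	Chromo 1	Chromodomains	800	867
CHD7	Helicase ATP-binding	Helicases	980	1154
CHD7	Helicase C-terminal	Helicases	1294	1464
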