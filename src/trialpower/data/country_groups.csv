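country,country_group
United States,Anglosphere
United Kingdom,Anglosphere
Canada,Anglosphere
Australia,Anglosphere
New Zealand,Anglosphere
Austria,Europe
Belgium,Europe
Croatia,Europe
Czech Republic,Europe
Denmark,Europe
Finland,Europe
France,Europe
Germany,Europe
Greece,Europe
Hungary,Europe
Ireland,Europe
Italy,Europe
Netherlands,Europe
Norway,Europe
Poland,Europe
Portugal,Europe
Slovenia,Europe
Spain,Europe
Sweden,Europe
Switzerland,Europe
Turkey,Non-western
Japan,Non-western
India,Non-western
China,Non-western
Israel,Non-western
Brazil,Non-western
Argentina,Non-western
Mexico,Non-western
Egypt,Non-western
Iran,Non-western
Korea,Non-western
Taiwan,Non-western
Thailand,Non-western
South Africa,Non-western
Nigeria,Non-western
Saudi Arabia,Non-western
Hong Kong,Non-western
Singapore,Non-western
Pakistan,Non-western
Indonesia,Non-western
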